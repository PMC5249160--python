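"""Minimal-media enumeration and rich-media configuration.

A minimal medium supplies exactly one carbon and one nitrogen source next to
fixed secondary nutrients (phosphate, sulfate, oxygen, minerals).  Starting
from a manually defined reference medium, alternative carbon sources are found
by removing the reference carbon source and exhaustively substituting every
other exchanged metabolite, keeping those that restore growth; likewise for
nitrogen.  The final media set is every (carbon, nitrogen) pairing that
supports wild-type growth, each source capped at the reference uptake rate.

"Metabolites" are operationalised as exchange reactions — the model's only
environmental interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fba import FbaProblem, GROWTH_TOL, Medium, UNBOUNDED
from .model import MetabolicModel

__all__ = ["MediaSet", "find_alternative_sources", "enumerate_minimal_media",
           "load_media_config", "load_rich_media", "media_set_to_dict"]


@dataclass
class MediaSet:
    """Result of minimal-media enumeration."""

    reference: Medium
    carbon_exchange: str
    nitrogen_exchange: str
    carbon_sources: list[str]
    nitrogen_sources: list[str]
    media: list[Medium] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.media)


def _grows(model: MetabolicModel, medium: Medium) -> bool:
    return FbaProblem(model, medium).solve().grows


def find_alternative_sources(model: MetabolicModel, reference: Medium,
                             role_exchange: str,
                             candidates: list[str] | None = None) -> list[str]:
    """Exchange reactions that can substitute for ``role_exchange``.

    Each candidate replaces the role exchange at the same uptake cap; it
    qualifies if the wild type still grows.  The original source is always a
    candidate (and qualifies by assumption, checked).  Raises if the
    reference medium itself does not support growth.
    """
    if role_exchange not in reference.uptake_limits:
        raise ValueError(
            f"{role_exchange!r} is not an uptake in medium {reference.name!r}"
        )
    if not _grows(model, reference):
        raise ValueError(
            f"reference medium {reference.name!r} does not support growth"
        )
    if candidates is None:
        candidates = [r.id for r in model.exchanges()]
    out = []
    for cand in sorted(set(candidates)):
        medium = (reference if cand == role_exchange
                  else reference.replace_source(role_exchange, cand))
        if _grows(model, medium):
            out.append(cand)
    return out


def enumerate_minimal_media(model: MetabolicModel, reference: Medium,
                            carbon_exchange: str, nitrogen_exchange: str,
                            allow_dual_role: bool = True,
                            carbon_sources: list[str] | None = None,
                            nitrogen_sources: list[str] | None = None
                            ) -> MediaSet:
    """All growth-supporting (carbon, nitrogen) source pairings.

    Candidate sources are discovered with :func:`find_alternative_sources`
    unless given.  Each emitted medium differs from the reference only in its
    carbon- and nitrogen-providing exchange, every one passes the wild-type
    growth test.  Dual-role metabolites (e.g. amino acids providing both
    carbon and nitrogen) may pair with themselves unless
    ``allow_dual_role=False``.
    """
    if carbon_sources is None:
        carbon_sources = find_alternative_sources(model, reference,
                                                  carbon_exchange)
    if nitrogen_sources is None:
        nitrogen_sources = find_alternative_sources(model, reference,
                                                    nitrogen_exchange)
    media = []
    for c in carbon_sources:
        for n in nitrogen_sources:
            if c == n and not allow_dual_role:
                continue
            medium = reference
            if c != carbon_exchange:
                medium = medium.replace_source(carbon_exchange, c)
            if n != nitrogen_exchange:
                if n == c:
                    # single dual-role source already present at the carbon cap
                    limits = dict(medium.uptake_limits)
                    limits.pop(nitrogen_exchange)
                    medium = Medium(medium.name, limits)
                else:
                    medium = medium.replace_source(nitrogen_exchange, n)
            medium = Medium(f"{c}|{n}", medium.uptake_limits)
            if _grows(model, medium):
                media.append(medium)
    return MediaSet(
        reference=reference,
        carbon_exchange=carbon_exchange,
        nitrogen_exchange=nitrogen_exchange,
        carbon_sources=list(carbon_sources),
        nitrogen_sources=list(nitrogen_sources),
        media=media,
    )


# -- configuration files ---------------------------------------------------
#
# YAML/JSON schema:
#   reference:
#     name: minimal-glc-nh4
#     carbon_exchange: EX_glc
#     nitrogen_exchange: EX_nh4
#     uptake: {EX_glc: 10, EX_nh4: 10, EX_o2: unbounded, ...}
#   rich_media:
#     - name: YPD
#       uptake: {EX_glc: 10, EX_his: unbounded, ...}


def _parse_uptake(entry: dict) -> dict[str, float]:
    out = {}
    for rid, cap in entry.items():
        if isinstance(cap, str) and cap.strip().lower() in ("unbounded", "inf"):
            out[rid] = UNBOUNDED
        else:
            out[rid] = float(cap)
    return out


def load_media_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_rich_media(config: dict, model: MetabolicModel) -> list[Medium]:
    """Parse manually defined (non-enumerated) media from a config mapping.

    Raises if any medium references an exchange id the model lacks; the
    error lists every unknown id.
    """
    known = {r.id for r in model.exchanges()}
    media = []
    unknown: list[str] = []
    for entry in config.get("rich_media", []):
        limits = _parse_uptake(entry.get("uptake", {}))
        unknown.extend(sorted(set(limits) - known))
        media.append(Medium(entry["name"], limits))
    if unknown:
        raise ValueError(f"rich media reference unknown exchange ids: {unknown}")
    return media


def reference_from_config(config: dict) -> tuple[Medium, str, str]:
    ref = config["reference"]
    medium = Medium(ref.get("name", "reference"), _parse_uptake(ref["uptake"]))
    return medium, ref["carbon_exchange"], ref["nitrogen_exchange"]


def media_set_to_dict(ms: MediaSet) -> dict:
    def enc(cap: float):
        return "unbounded" if cap == UNBOUNDED else cap

    return {
        "reference": ms.reference.name,
        "carbon_exchange": ms.carbon_exchange,
        "nitrogen_exchange": ms.nitrogen_exchange,
        "carbon_sources": ms.carbon_sources,
        "nitrogen_sources": ms.nitrogen_sources,
        "media": [
            {"name": m.name,
             "uptake": {k: enc(v) for k, v in sorted(m.uptake_limits.items())}}
            for m in ms.media
        ],
    }
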