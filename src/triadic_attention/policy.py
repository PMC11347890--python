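"""Normative reference and intervention-recommendation policy.

A participant's session profile is compared against a nonautistic (NA)
normative reference: a domain is flagged when the observed value deviates
from the NA mean by at least ``sd_multiplier`` (default 2) NA standard
deviations in a direction configured per domain.  Directions follow the
behavioral reading of each statistic -- e.g. making *more* contacts per
minute than the norm, or making no exclusions at all, never triggers
feedback.  When more than ``max_domains`` (default 3) domains are flagged,
the ones with the largest standardized deviations are selected.

The shipped reference values are group statistics over 8 nonautistic
participants (AvgCon 6.09 (0.94) frames, AvgNoCon 30.95 (15.11) frames,
NumCon 2.14 (0.47) per minute, MaxExc 9.38 (5.89) frames, ExcPct 3.13
(1.85) %), stored as an editable JSON asset, not constants.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources

from .profiles import DOMAINS, SessionProfile

__all__ = [
    "DomainReference",
    "NormativeReference",
    "InterventionRecommendation",
    "compute_thresholds",
    "flag_domains",
    "select_interventions",
]


@dataclass(frozen=True)
class DomainReference:
    """NA mean/SD and flag directions for one domain."""

    na_mean: float
    na_sd: float
    flag_high: bool
    flag_low: bool
    asc_mean: float | None = None  # informational only

    def __post_init__(self):
        if not self.na_sd > 0:
            raise ValueError("na_sd must be positive")
        if not (self.flag_high or self.flag_low):
            raise ValueError("at least one flag direction must be enabled")


@dataclass(frozen=True)
class NormativeReference:
    """Per-domain normative values plus the global SD multiplier."""

    domains: dict[str, DomainReference]
    sd_multiplier: float = 2.0

    def __post_init__(self):
        if not self.sd_multiplier > 0:
            raise ValueError("sd_multiplier must be positive")
        unknown = set(self.domains) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown domains: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeReference":
        domains = {name: DomainReference(**vals) for name, vals in d["domains"].items()}
        return cls(domains=domains, sd_multiplier=float(d.get("sd_multiplier", 2.0)))

    @classmethod
    def from_json(cls, path) -> "NormativeReference":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "NormativeReference":
        text = resources.files("triadic_attention").joinpath("data/normative_reference.json").read_text()
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return {
            "sd_multiplier": self.sd_multiplier,
            "domains": {
                name: {
                    "na_mean": ref.na_mean,
                    "na_sd": ref.na_sd,
                    "flag_high": ref.flag_high,
                    "flag_low": ref.flag_low,
                    "asc_mean": ref.asc_mean,
                }
                for name, ref in self.domains.items()
            },
        }


@dataclass(frozen=True)
class InterventionRecommendation:
    """One flagged domain: direction, observed value and standardized deviation."""

    domain: str
    direction: str  # "high" | "low"
    observed: float
    threshold: float
    deviation_sds: float


def compute_thresholds(ref: NormativeReference) -> dict[str, dict[str, float]]:
    """Per-domain flag bounds: mean + m*SD where flag_high, mean - m*SD where flag_low.

    Returned values are unrounded; round to 2 decimals for reporting only.
    """
    out: dict[str, dict[str, float]] = {}
    for name, dom in ref.domains.items():
        bounds: dict[str, float] = {}
        if dom.flag_high:
            bounds["upper"] = dom.na_mean + ref.sd_multiplier * dom.na_sd
        if dom.flag_low:
            bounds["lower"] = dom.na_mean - ref.sd_multiplier * dom.na_sd
        out[name] = bounds
    return out


def flag_domains(
    profile: SessionProfile, ref: NormativeReference | None = None
) -> list[InterventionRecommendation]:
    """Flag every domain deviating >= sd_multiplier NA SDs in a flagged direction.

    The comparison is inclusive at the threshold.  Domains with an undefined
    observed value (e.g. AvgCon with zero contacts) are skipped with a warning.
    """
    ref = ref or NormativeReference.default()
    thresholds = compute_thresholds(ref)
    flagged: list[InterventionRecommendation] = []
    for name in DOMAINS:
        if name not in ref.domains:
            continue
        dom = ref.domains[name]
        observed = profile.domain_value(name)
        if observed is None or (isinstance(observed, float) and math.isnan(observed)):
            warnings.warn(f"domain {name} undefined for this session; skipped", stacklevel=2)
            continue
        deviation = (observed - dom.na_mean) / dom.na_sd
        bounds = thresholds[name]
        if dom.flag_high and observed >= bounds["upper"]:
            flagged.append(
                InterventionRecommendation(
                    domain=name,
                    direction="high",
                    observed=float(observed),
                    threshold=bounds["upper"],
                    deviation_sds=float(deviation),
                )
            )
        elif dom.flag_low and observed <= bounds["lower"]:
            flagged.append(
                InterventionRecommendation(
                    domain=name,
                    direction="low",
                    observed=float(observed),
                    threshold=bounds["lower"],
                    deviation_sds=float(deviation),
                )
            )
    return flagged


def select_interventions(
    flagged: list[InterventionRecommendation], max_domains: int = 3
) -> list[InterventionRecommendation]:
    """Keep at most ``max_domains`` recommendations, largest |deviation| first.

    Ties are broken by the fixed domain order (AvgCon, AvgNoCon, NumCon,
    MaxExc, ExcPct).  Output preserves that domain order.
    """
    if len(flagged) <= max_domains:
        return list(flagged)
    order = {name: i for i, name in enumerate(DOMAINS)}
    ranked = sorted(flagged, key=lambda r: (-abs(r.deviation_sds), order[r.domain]))
    chosen = ranked[:max_domains]
    chosen.sort(key=lambda r: order[r.domain])
    return chosen
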