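"""Synthetic ED cohort generator with known ground truth.

The real study populations (five hospital systems, 74.6K-144.9K visits,
288-686 unique complaints, critical-outcome prevalence 1.7-3.5%) are
private, so every other module is exercised on simulated cohorts that
reproduce the statistical structure the method assumes:

* a two-level complaint hierarchy with a long-tailed (power-law) complaint
  frequency distribution;
* the standard triage predictor blocks (age band, gender, arrival mode,
  five discretized vitals with a missing category);
* a rare binary outcome drawn from a logistic model whose linear predictor
  combines demographic/vital effects, a per-category effect, and — only for
  a known informative subset S of complaints — a complaint-specific
  log-odds shift of +/- delta.  Complaints outside S carry no signal beyond
  their category, which is exactly the structure the specification search
  is meant to discover.

The intercept is calibrated by bisection so the expected prevalence matches
the target.  Everything is reproducible from the config seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import (
    AGE_BANDS,
    ARRIVAL_MODES,
    FIELD_LABELS,
    GENDERS,
    MISSING,
    VITAL_NAMES,
    Cohort,
    ComplaintHierarchy,
    SpecificationMask,
)
from .errors import ValidationError
from .ga import GAResult

#: normal-range bin per vital (bulk of the probability mass goes here)
_NORMAL_BIN = {
    "temperature": "96.1-99.2",
    "pulse": "59-105",
    "respiratory_rate": "14-19",
    "blood_pressure": "106-176",
    "oxygen_saturation": ">94",
}

#: marginal age-band distribution (adult ED visits skew young)
_AGE_PROBS = (0.22, 0.17, 0.15, 0.14, 0.12, 0.10, 0.07, 0.03)


@dataclass(frozen=True)
class SyntheticConfig:
    n_patients: int = 50_000
    n_categories: int = 5
    complaints_per_category: tuple[int, int] = (8, 8)  # inclusive min/max
    informative_complaint_count: int = 8
    specific_effect: float = 0.8        # |delta|, log-odds; signs split +/-
    category_effect_sd: float = 0.5     # log-odds sd of per-category effects
    demographic_effect_sd: float = 0.3  # log-odds sd of demographic/vital level effects
    target_prevalence: float = 0.03
    frequency_skew: float = 1.2         # power-law exponent of complaint frequencies
    missing_rate: float = 0.05          # per-vital missing-category mass
    ambulance_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValidationError("target_prevalence must be in (0, 1)")
        if self.n_patients < 1 or self.n_categories < 1:
            raise ValidationError("counts must be positive")
        lo, hi = self.complaints_per_category
        if lo < 1 or hi < lo:
            raise ValidationError("complaints_per_category must be a valid (min, max)")
        if self.informative_complaint_count > self.n_categories * hi:
            raise ValidationError("informative_complaint_count exceeds total complaints")
        if self.specific_effect < 0 or self.category_effect_sd < 0:
            raise ValidationError("effect sizes must be non-negative")


#: scale presets named after the five study populations (sample size,
#: approximate unique-complaint count, outcome prevalence)
POPULATION_PRESETS: dict[str, SyntheticConfig] = {
    name: SyntheticConfig(
        n_patients=n, n_categories=cats, complaints_per_category=(span - 2, span + 2),
        informative_complaint_count=max(8, (cats * span) // 5),
        target_prevalence=prev, seed=0,
    )
    for name, (n, cats, span, prev) in {
        "ACAD": (104_500, 86, 8, 0.0345),
        "COMM": (144_900, 77, 8, 0.0348),
        "BRAZIL": (94_800, 45, 8, 0.0300),
        "UAE": (103_500, 36, 8, 0.0168),
        "NAT": (74_600, 81, 8, 0.0305),
    }.items()
}


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery scoring."""

    hierarchy: ComplaintHierarchy
    informative: dict[str, float]          # complaint -> signed delta
    category_effects: dict[str, float]
    demographic_effects: dict[str, dict[str, float]]
    intercept: float
    seed: int

    @property
    def informative_mask(self) -> SpecificationMask:
        return SpecificationMask.from_selected(self.hierarchy, self.informative)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["hierarchy"] = {
            "complaints": list(self.hierarchy.complaints),
            "parent": dict(self.hierarchy.parent),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _build_hierarchy(config: SyntheticConfig, rng: np.random.Generator) -> ComplaintHierarchy:
    lo, hi = config.complaints_per_category
    counts = rng.integers(lo, hi + 1, size=config.n_categories)
    pairs = []
    k = 0
    for g in range(config.n_categories):
        cat = f"grp{g + 1:03d}"
        for _ in range(int(counts[g])):
            k += 1
            pairs.append((f"c{k:04d}", cat))
    return ComplaintHierarchy.from_pairs(pairs)


def _complaint_distribution(n: int, skew: float, rng: np.random.Generator) -> np.ndarray:
    """Power-law frequencies over a random rank assignment of complaints."""
    ranks = rng.permutation(n) + 1
    p = ranks.astype(float) ** (-skew)
    return p / p.sum()


def _pick_informative(
    probs: np.ndarray, count: int, delta: float, rng: np.random.Generator
) -> dict[int, float]:
    """Sample the informative set from mid-frequency complaints.

    Ubiquitous complaints would make recovery trivial and singleton
    complaints would make it hopeless, so candidates come from the middle
    half of the frequency ranking (padded outward if the window is small).
    """
    n = len(probs)
    order = np.argsort(-probs, kind="stable")
    lo, hi = n // 4, max(n // 4 + count, (3 * n) // 4)
    window = order[lo:hi]
    if len(window) < count:
        window = order
    chosen = rng.choice(window, size=count, replace=False)
    signs = np.ones(count)
    signs[count // 2:] = -1.0
    signs = signs[rng.permutation(count)]
    return {int(c): float(s * delta) for c, s in zip(chosen, signs)}


def _vital_probs(vital: str, missing_rate: float) -> np.ndarray:
    labels = FIELD_LABELS[vital]
    probs = np.empty(len(labels))
    rest = 1.0 - missing_rate
    normal = labels.index(_NORMAL_BIN[vital])
    n_other = len(labels) - 2  # non-normal, non-missing
    for i, lab in enumerate(labels):
        if lab == MISSING:
            probs[i] = missing_rate
        elif i == normal:
            probs[i] = 0.70 * rest
        else:
            probs[i] = 0.30 * rest / n_other
    return probs


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Bisection on c so that mean(sigmoid(lp + c)) == target."""
    lo, hi = -40.0, 40.0
    f = lambda c: float(np.mean(1.0 / (1.0 + np.exp(-(lp + c))))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValidationError("target prevalence unreachable given the effects")
    for _ in range(100):
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort and the ground truth that generated it."""
    rng = np.random.default_rng(config.seed)
    hierarchy = _build_hierarchy(config, rng)
    n = hierarchy.n
    n_pat = config.n_patients

    comp_probs = _complaint_distribution(n, config.frequency_skew, rng)
    comp_codes = rng.choice(n, size=n_pat, p=comp_probs)
    cat_codes = hierarchy.parent_codes[comp_codes]

    informative = _pick_informative(
        comp_probs, config.informative_complaint_count, config.specific_effect, rng
    )
    delta = np.zeros(n)
    for idx, d in informative.items():
        delta[idx] = d
    gamma = rng.normal(0.0, config.category_effect_sd, len(hierarchy.categories))

    frame: dict[str, np.ndarray] = {}
    lp = delta[comp_codes] + gamma[cat_codes]
    demo_effects: dict[str, dict[str, float]] = {}
    marginals = {
        "age_band": np.array(_AGE_PROBS),
        "gender": np.array([0.52, 0.48]),
        "arrival_mode": np.array([1 - config.ambulance_rate, config.ambulance_rate]),
        **{v: _vital_probs(v, config.missing_rate) for v in VITAL_NAMES},
    }
    for fieldname, probs in marginals.items():
        labels = FIELD_LABELS[fieldname]
        codes = rng.choice(len(labels), size=n_pat, p=probs)
        effects = rng.normal(0.0, config.demographic_effect_sd, len(labels))
        effects -= effects @ probs  # center so the intercept carries the level
        lp += effects[codes]
        frame[fieldname] = np.array(labels, dtype=object)[codes]
        demo_effects[fieldname] = {lab: float(e) for lab, e in zip(labels, effects)}

    intercept = _calibrate_intercept(lp, config.target_prevalence)
    p = 1.0 / (1.0 + np.exp(-(lp + intercept)))
    outcome = (rng.random(n_pat) < p).astype(np.int8)
    if outcome.min() == outcome.max():
        raise ValidationError(
            "generated cohort has a single outcome class; increase n_patients"
        )

    frame["complaint"] = np.array(hierarchy.complaints, dtype=object)[comp_codes]
    frame["outcome"] = outcome
    cohort = Cohort(pd.DataFrame(frame), hierarchy)
    truth = GroundTruth(
        hierarchy=hierarchy,
        informative={hierarchy.complaints[i]: d for i, d in sorted(informative.items())},
        category_effects={g: float(e) for g, e in zip(hierarchy.categories, gamma)},
        demographic_effects=demo_effects,
        intercept=float(intercept),
        seed=config.seed,
    )
    return cohort, truth


def recovery_metrics(
    result: GAResult | SpecificationMask, truth: GroundTruth
) -> tuple[float, float]:
    """(sensitivity, specificity) of a selected set against the planted set S.

    Sensitivity = |selected ∩ S| / |S|; specificity = |excluded ∩ S̄| / |S̄|.
    """
    mask = result.best_mask if isinstance(result, GAResult) else result
    if len(mask) != truth.hierarchy.n:
        raise ValidationError("mask length does not match the truth's hierarchy")
    truth_bits = truth.informative_mask.bits.astype(bool)
    sel = mask.bits.astype(bool)
    n_s = int(truth_bits.sum())
    n_c = len(sel) - n_s
    sensitivity = float((sel & truth_bits).sum() / n_s) if n_s else float("nan")
    specificity = float((~sel & ~truth_bits).sum() / n_c) if n_c else float("nan")
    return sensitivity, specificity
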