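"""Synthetic phantom cohorts: brain-like volumes plus covariate tables.

The real study populations are not redistributable, so every stage of
the pipeline is exercised on synthetic stand-ins with controllable
signal:

* **Volumes** are 3D ellipsoidal "brain" phantoms with an inner
  low-intensity "ventricle" whose size is drawn from a class-dependent
  distribution (an atrophy proxy — enlarged ventricles in the aMCI
  class), plus Gaussian noise.  The proxy is a modeling convenience for
  giving the image channel a controllable class signal, not a claim
  about aMCI anatomy.
* **Covariate tables** draw the five participant variables from
  configurable marginal distributions (presets reproduce the published
  cohort summaries) with a configurable APOE-ε4 / diagnosis association
  expressed as an odds ratio.

Everything is a deterministic function of its seed; per-participant
volume seeds are derived by hashing the cohort seed with the
participant id, so cohorts are reproducible while volumes stay
independent.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
from scipy.optimize import brentq

from .cohort import (
    CohortTable,
    ParticipantRecord,
    Scheme,
    age_bins,
)
from .enhancement import PreparedVolume, volume_from_array

__all__ = [
    "PhantomParams",
    "CohortParams",
    "HNR_MARGINALS",
    "ADNI_MARGINALS",
    "hnr_cohort_params",
    "adni_cohort_params",
    "mechanism_cohort_params",
    "simulate_volume",
    "simulate_metadata",
    "simulate_cohort",
    "participant_seed",
]

# Category counts of the two published cohort summaries; the synthetic
# generator's marginals and the acceptance worked examples both derive
# from these.
HNR_MARGINALS: dict[str, dict[str, int]] = {
    "age": {"46-55": 2, "56-65": 25, "66-75": 64, "76-85": 29},
    "gender": {"Female": 48, "Male": 72},
    "education": {"<=10": 27, "11-13": 69, ">=14": 24},
    "marital_status": {"Married": 96, "Widowed": 14, "Divorced": 7, "Single": 2},
    "apoe4": {"Positive": 33, "Negative": 87},
    "label": {"aMCI": 61, "Control": 59},
}

ADNI_MARGINALS: dict[str, dict[str, int]] = {
    "age": {"46-55": 3, "56-65": 58, "66-75": 270, "76-90": 293},
    "gender": {"Female": 250, "Male": 374},
    "education": {"<=10": 30, "11-13": 109, ">=14": 485},
    "marital_status": {"Married": 473, "Widowed": 87, "Divorced": 42, "Single": 22},
    "apoe4": {"Positive": 352, "Negative": 272},
    "label": {"aMCI": 397, "Control": 227},
}

# Integer age/education ranges used when drawing a raw value uniformly
# inside a sampled bin.
_EDUCATION_RANGES = {"<=10": (6, 10), "11-13": (11, 13), ">=14": (14, 18)}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and noise of the ellipsoid brain phantom.

    Intensities are on an arbitrary scale (the volume is min-max scaled
    to 8-bit afterwards).  ``atrophy_mean_*`` scale the base ventricle
    radii per class; the aMCI mean is larger, enlarging the
    low-intensity ventricle.
    """

    depth: int = 192
    slice_size: tuple[int, int] = (224, 224)
    brain_intensity: float = 180.0
    ventricle_intensity: float = 30.0
    brain_radii: tuple[float, float, float] = (80.0, 95.0, 78.0)  # (z, y, x)
    ventricle_radii: tuple[float, float, float] = (20.0, 26.0, 16.0)
    atrophy_mean_control: float = 1.0
    atrophy_mean_amci: float = 1.35
    atrophy_sd: float = 0.08
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.depth < 167:
            raise ValueError(f"phantom depth must be >= 167, got {self.depth}")
        worst = (self.atrophy_mean_amci + 6 * self.atrophy_sd)
        for v, b in zip(self.ventricle_radii, self.brain_radii):
            if v * worst >= b:
                raise ValueError(
                    "ventricle radii (after atrophy scaling) must stay strictly "
                    "inside the brain ellipsoid"
                )


@dataclass(frozen=True)
class CohortParams:
    """Covariate-table generator settings.

    ``marginals`` are per-variable category weights (counts or
    probabilities); ``apoe_amci_association`` is the odds ratio of
    APOE-ε4 positivity in aMCI vs control participants (1.0 means
    independence).
    """

    n: int = 120
    amci_fraction: float = 61 / 120
    marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: HNR_MARGINALS
    )
    apoe_amci_association: float = 1.0
    scheme: Scheme = Scheme.HNR
    #: fixed-count draws instead of i.i.d. sampling: exactly
    #: round(n * amci_fraction) aMCI labels, and the APOE-ε4 positives
    #: allocated per class at the tilted per-class rates (shuffled).
    #: Removes sampling variance in the covariate-label association;
    #: used by the signal-injection preset.
    exact_balance: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be >= 2")
        if not 0.0 < self.amci_fraction < 1.0:
            raise ValueError("amci_fraction must be in (0, 1)")
        if self.apoe_amci_association <= 0:
            raise ValueError("odds ratio must be positive")
        for var in ("age", "gender", "education", "marital_status", "apoe4"):
            weights = self.marginals.get(var)
            if not weights:
                raise ValueError(f"missing marginals for {var}")
            if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
                raise ValueError(f"infeasible marginals for {var}: {dict(weights)}")


def hnr_cohort_params(
    apoe_amci_association: float | None = None,
) -> CohortParams:
    """Cohort parameters matching the published population-study summary.

    The default association reproduces the summary's implied APOE-ε4
    odds ratio (21/40 vs 12/47 ≈ 2.06).
    """
    if apoe_amci_association is None:
        apoe_amci_association = (21 / 40) / (12 / 47)
    return CohortParams(
        n=120, amci_fraction=61 / 120, marginals=HNR_MARGINALS,
        apoe_amci_association=apoe_amci_association, scheme=Scheme.HNR,
    )


def adni_cohort_params(apoe_amci_association: float | None = None) -> CohortParams:
    """Cohort parameters matching the ADNI-style summary table."""
    if apoe_amci_association is None:
        apoe_amci_association = (185 / 212) / (167 / 60)
    return CohortParams(
        n=624, amci_fraction=397 / 624, marginals=ADNI_MARGINALS,
        apoe_amci_association=apoe_amci_association, scheme=Scheme.ADNI,
    )


def mechanism_cohort_params(
    n: int = 40, apoe_amci_association: float = 10.0
) -> CohortParams:
    """Balanced cohort for signal-injection experiments.

    Classes and the APOE-ε4 marginal are balanced (maximizing the
    information the tilted covariate carries about the label); the
    remaining marginals follow the population-study summary.
    """
    marginals = dict(HNR_MARGINALS)
    marginals["apoe4"] = {"Positive": 1, "Negative": 1}
    return CohortParams(
        n=n, amci_fraction=0.5, marginals=marginals,
        apoe_amci_association=apoe_amci_association, scheme=Scheme.HNR,
        exact_balance=True,
    )


def participant_seed(cohort_seed: int, participant_id: str) -> int:
    """Stable per-participant seed below 2**31."""
    digest = hashlib.sha256(f"{cohort_seed}:{participant_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def simulate_volume(
    label: str, params: PhantomParams | None = None, seed: int = 0
) -> PreparedVolume:
    """One phantom scan for a participant with the given label.

    An ellipsoidal brain with an inner ventricle whose radius scale is
    drawn from the label's atrophy distribution, plus Gaussian noise,
    min-max scaled to 8-bit.
    """
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    mean = params.atrophy_mean_amci if label == "aMCI" else params.atrophy_mean_control
    scale = mean + params.atrophy_sd * rng.standard_normal()
    scale = float(np.clip(scale, 0.2, mean + 6 * params.atrophy_sd))

    depth, (ny, nx) = params.depth, params.slice_size
    z = (np.arange(depth) - (depth - 1) / 2.0)[:, None, None]
    y = (np.arange(ny) - (ny - 1) / 2.0)[None, :, None]
    x = (np.arange(nx) - (nx - 1) / 2.0)[None, None, :]
    bz, by, bx = params.brain_radii
    vz, vy, vx = (r * scale for r in params.ventricle_radii)
    brain = (z / bz) ** 2 + (y / by) ** 2 + (x / bx) ** 2 <= 1.0
    ventricle = (z / vz) ** 2 + (y / vy) ** 2 + (x / vx) ** 2 <= 1.0

    volume = np.zeros((depth, ny, nx), dtype=np.float64)
    volume[brain] = params.brain_intensity
    volume[ventricle] = params.ventricle_intensity
    if params.noise_sd > 0:
        volume += params.noise_sd * rng.standard_normal(volume.shape)
    return volume_from_array(volume, source_format="phantom")


def _tilted_apoe_probabilities(
    p_marginal: float, amci_fraction: float, odds_ratio: float
) -> tuple[float, float]:
    """Per-class P(APOE+) with the given mixture marginal and odds ratio."""
    if odds_ratio == 1.0 or p_marginal in (0.0, 1.0):
        return p_marginal, p_marginal

    def p_amci(p_c: float) -> float:
        odds_c = p_c / (1.0 - p_c)
        odds_a = odds_ratio * odds_c
        return odds_a / (1.0 + odds_a)

    def mixture_gap(p_c: float) -> float:
        return (
            amci_fraction * p_amci(p_c)
            + (1.0 - amci_fraction) * p_c
            - p_marginal
        )

    eps = 1e-9
    p_control = brentq(mixture_gap, eps, 1.0 - eps)
    return p_amci(p_control), p_control


def simulate_metadata(
    n: int | None = None, params: CohortParams | None = None, seed: int = 0
) -> CohortTable:
    """Draw a covariate table with the configured marginals.

    Labels are i.i.d. Bernoulli(``amci_fraction``); covariates are drawn
    from their marginals independently of the label, except APOE-ε4,
    whose per-class probabilities are tilted so that the odds ratio of
    positivity between aMCI and control equals
    ``apoe_amci_association`` while the mixture marginal is preserved.
    Raw ages (and education years) are drawn uniformly inside the
    sampled bin.
    """
    params = params or CohortParams()
    if n is None:
        n = params.n
    rng = np.random.default_rng(seed)

    def normalized(var: str) -> tuple[list[str], np.ndarray]:
        weights = params.marginals[var]
        cats = list(weights)
        w = np.array([weights[c] for c in cats], dtype=float)
        return cats, w / w.sum()

    apoe_cats, apoe_probs = normalized("apoe4")
    p_pos = float(apoe_probs[apoe_cats.index("Positive")])
    p_pos_amci, p_pos_control = _tilted_apoe_probabilities(
        p_pos, params.amci_fraction, params.apoe_amci_association
    )

    bin_bounds = {}
    for label_ in age_bins(params.scheme):
        lo, hi = label_.split("-")
        bin_bounds[label_] = (int(lo.lstrip("<=>")), int(hi))

    if params.exact_balance:
        n_amci = int(round(n * params.amci_fraction))
        fixed_labels = np.array(["aMCI"] * n_amci + ["Control"] * (n - n_amci))
        rng.shuffle(fixed_labels)
        fixed_apoe: dict[str, list] = {}
        for lab, count, p_apoe in (
            ("aMCI", n_amci, p_pos_amci),
            ("Control", n - n_amci, p_pos_control),
        ):
            n_positive = int(round(count * p_apoe))
            draw = np.array(["Positive"] * n_positive
                            + ["Negative"] * (count - n_positive))
            rng.shuffle(draw)
            fixed_apoe[lab] = list(draw)
    else:
        fixed_labels = None
        fixed_apoe = None

    records = []
    for i in range(n):
        if fixed_labels is not None:
            label = str(fixed_labels[i])
        else:
            label = "aMCI" if rng.random() < params.amci_fraction else "Control"
        age_cats, age_probs = normalized("age")
        age_bin = age_cats[rng.choice(len(age_cats), p=age_probs)]
        lo, hi = bin_bounds[age_bin]
        age = int(rng.integers(lo, hi + 1))
        gender_cats, gender_probs = normalized("gender")
        gender = gender_cats[rng.choice(len(gender_cats), p=gender_probs)]
        edu_cats, edu_probs = normalized("education")
        edu_bin = edu_cats[rng.choice(len(edu_cats), p=edu_probs)]
        elo, ehi = _EDUCATION_RANGES[edu_bin]
        education = int(rng.integers(elo, ehi + 1))
        mar_cats, mar_probs = normalized("marital_status")
        marital = mar_cats[rng.choice(len(mar_cats), p=mar_probs)]
        if fixed_apoe is not None:
            apoe = fixed_apoe[label].pop()
        else:
            p_apoe = p_pos_amci if label == "aMCI" else p_pos_control
            apoe = "Positive" if rng.random() < p_apoe else "Negative"
        records.append(
            ParticipantRecord(
                participant_id=f"P{i:04d}",
                age=age,
                gender=gender,
                education_years=education,
                marital_status=marital,
                apoe4=apoe,
                label=label,
            )
        )
    return CohortTable(records=tuple(records), scheme=params.scheme)


def simulate_cohort(
    cohort_params: CohortParams | None = None,
    phantom_params: PhantomParams | None = None,
    image_signal: bool = True,
    metadata_signal: bool = True,
    seed: int = 0,
) -> tuple[CohortTable, dict[str, PreparedVolume]]:
    """A full synthetic cohort: covariate table plus one volume each.

    ``image_signal=False`` equalizes the atrophy means across classes
    (volumes carry no label information); ``metadata_signal=False``
    forces the APOE-ε4 odds ratio to 1 (no covariate carries label
    information, since the others are independent of the label by
    construction).  Volume seeds derive from (seed, participant_id).
    """
    cohort_params = cohort_params or CohortParams()
    phantom_params = phantom_params or PhantomParams()
    if not metadata_signal:
        cohort_params = replace(cohort_params, apoe_amci_association=1.0)
    if not image_signal:
        phantom_params = replace(
            phantom_params,
            atrophy_mean_amci=phantom_params.atrophy_mean_control,
        )
    cohort = simulate_metadata(params=cohort_params, seed=seed)
    volumes = {
        r.participant_id: simulate_volume(
            r.label, phantom_params, participant_seed(seed, r.participant_id)
        )
        for r in cohort
    }
    return cohort, volumes
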