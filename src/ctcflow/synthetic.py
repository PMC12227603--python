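"""Synthetic data with the statistical structure the analysis assumes.

Four generators, one per downstream stage:

* flow-cytometry events — a mixture of populations (leukocytes, CTCs) with
  per-channel log-normal stain signals riding on an autofluorescence
  baseline, mixed through a spillover matrix;
* single-stain compensation controls — one table per channel, stained on
  that channel only;
* patient cohorts — group membership (A/B/C), group-conditional HER2
  intensity and EMT-index coupled through a Gaussian copula at a target
  Spearman correlation, exponential progression-free survival with uniform
  administrative censoring;
* binary gene x sample mutation matrices — independent Bernoulli calls with
  group- and source-dependent rates.

Everything is driven by one integer seed; all internal streams derive from
it deterministically, so identical (spec, seed) gives byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ctcflow.channels import CHANNELS
from ctcflow.errors import ValidationError
from ctcflow.gating import SpilloverMatrix
from ctcflow.her2 import classify_her2

__all__ = [
    "CohortSpec",
    "MutationModel",
    "PopulationSpec",
    "ctc_population",
    "default_cohort_spec",
    "default_mutation_model",
    "default_spillover",
    "leukocyte_population",
    "simulate_cohort",
    "simulate_events",
    "simulate_mutation_matrix",
    "simulate_single_stain_controls",
]

GROUPS = ("A", "B", "C")
SOURCES = ("CTC", "tissue")


# --------------------------------------------------------------------------
# flow-cytometry events
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """One stained cell population.

    Stain signal on each channel is log-normal: median ``exp(log_median)``
    with log-scale ``log_sigma``.  The measured intensity is
    ``baseline + stain`` before spillover mixing.  Channels without stain
    use ``log_median = -inf`` convention via a 0 entry in ``stain_median``.
    """

    name: str
    fraction: float
    stain_median: Mapping[str, float]  # median stain intensity per channel
    log_sigma: Mapping[str, float]
    baseline: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValidationError(
                f"fraction must be in [0,1], got {self.fraction}"
            )
        for coll, positive in (
            (self.stain_median, False),
            (self.log_sigma, True),
            (self.baseline, False),
        ):
            for chan in CHANNELS:
                if chan not in coll:
                    raise ValidationError(f"missing channel {chan!r}")
                v = coll[chan]
                if positive and v <= 0:
                    raise ValidationError(f"log_sigma[{chan!r}] must be > 0")
                if not positive and v < 0:
                    raise ValidationError(f"{chan!r} value must be >= 0")

    def draw_stain(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, 5) stain signals, channel order as CHANNELS."""
        out = np.zeros((n, len(CHANNELS)))
        for k, chan in enumerate(CHANNELS):
            med = self.stain_median[chan]
            if med > 0:
                out[:, k] = med * np.exp(
                    self.log_sigma[chan] * rng.standard_normal(n)
                )
        return out


_DEFAULT_BASELINE = {c: 5.0 for c in CHANNELS}
_DEFAULT_SIGMA = {c: 0.45 for c in CHANNELS}


def leukocyte_population(fraction: float) -> PopulationSpec:
    """White blood cells: nucleated, CD45-bright, vimentin-positive,
    essentially cytokeratin- and HER2-dark."""
    return PopulationSpec(
        name="leukocyte",
        fraction=fraction,
        stain_median={
            "hoechst": 500.0, "ck": 4.0, "vim": 80.0,
            "cd45": 400.0, "her2": 4.0,
        },
        log_sigma=dict(_DEFAULT_SIGMA),
        baseline=dict(_DEFAULT_BASELINE),
    )


def ctc_population(
    fraction: float, her2_median: float = 100.0, emt_index: float = 0.17
) -> PopulationSpec:
    """Tumor cells: nucleated, cytokeratin-bright, CD45-dark; vimentin set
    from the target EMT-index against a fixed cytokeratin median."""
    ck = 400.0
    if not 0 <= emt_index < 1:
        raise ValidationError("emt_index must be in [0, 1)")
    vim = ck * emt_index / (1.0 - emt_index)
    return PopulationSpec(
        name="ctc",
        fraction=fraction,
        stain_median={
            "hoechst": 500.0, "ck": ck, "vim": vim,
            "cd45": 4.0, "her2": her2_median,
        },
        log_sigma=dict(_DEFAULT_SIGMA),
        baseline=dict(_DEFAULT_BASELINE),
    )


def default_spillover() -> SpilloverMatrix:
    """Mild optical cross-talk between spectrally adjacent fluorophores."""
    S = np.eye(len(CHANNELS))
    idx = {c: i for i, c in enumerate(CHANNELS)}
    # FITC -> PE is the classic overlap; PE -> PE-Cy7 and FITC residuals minor
    S[idx["ck"], idx["vim"]] = 0.12
    S[idx["vim"], idx["cd45"]] = 0.06
    S[idx["vim"], idx["ck"]] = 0.03
    S[idx["cd45"], idx["her2"]] = 0.02
    return SpilloverMatrix(S)


def _mix_and_frame(
    stain: np.ndarray,
    baseline: np.ndarray,
    spillover: SpilloverMatrix,
    labels: Sequence[str] | None,
) -> pd.DataFrame:
    measured = baseline + stain @ spillover.values
    frame = pd.DataFrame(measured, columns=list(CHANNELS))
    frame.insert(0, "event_id", np.arange(len(frame)))
    if labels is not None:
        frame["truth_pop"] = list(labels)
    frame.attrs["compensated"] = False
    return frame


def simulate_events(
    populations: Sequence[PopulationSpec],
    spillover: SpilloverMatrix,
    n_events: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate a mixed event table.

    Population membership is multinomial over the specified fractions; true
    stain signals are drawn per population, mixed through the spillover
    matrix, and the population label is retained in a ``truth_pop`` column
    as hidden ground truth.
    """
    if n_events < 1:
        raise ValidationError("n_events must be >= 1")
    fractions = np.array([p.fraction for p in populations])
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"population fractions must sum to 1, got {fractions.sum():.6g}"
        )
    rng = np.random.default_rng(seed)
    membership = rng.choice(len(populations), size=n_events, p=fractions)
    stain = np.zeros((n_events, len(CHANNELS)))
    labels = np.empty(n_events, dtype=object)
    for i, pop in enumerate(populations):
        mask = membership == i
        stain[mask] = pop.draw_stain(int(mask.sum()), rng)
        labels[mask] = pop.name
    baseline = np.array([populations[0].baseline[c] for c in CHANNELS])
    return _mix_and_frame(stain, baseline, spillover, labels)


def simulate_single_stain_controls(
    spec: PopulationSpec,
    spillover: SpilloverMatrix,
    n_events: int,
    seed: int,
) -> dict[str, pd.DataFrame]:
    """One control table per channel, stained on that channel only.

    For control k the only stain signal is on channel k; the other channels
    read baseline plus whatever spills over from k.  These tables feed
    :func:`ctcflow.gating.estimate_spillover`.
    """
    if n_events < 1:
        raise ValidationError("n_events must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(len(CHANNELS))
    baseline = np.array([spec.baseline[c] for c in CHANNELS])
    controls: dict[str, pd.DataFrame] = {}
    for k, chan in enumerate(CHANNELS):
        rng = np.random.default_rng(seeds[k])
        stain = np.zeros((n_events, len(CHANNELS)))
        stain[:, k] = spec.stain_median[chan] * np.exp(
            spec.log_sigma[chan] * rng.standard_normal(n_events)
        )
        controls[chan] = _mix_and_frame(stain, baseline, spillover, None)
    return controls


# --------------------------------------------------------------------------
# patient cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of a simulated patient cohort.

    Per-group HER2 intensity is log-normal (given as median + log-scale),
    truncated above the positivity cutoff for group B and at-or-below it for
    group C so CTC HER2 status is consistent with group by construction.
    The EMT-index is logit-normal, coupled to HER2 intensity through a
    Gaussian copula at Spearman correlation ``coupling``.  PFS is
    exponential per group with uniform administrative censoring calibrated
    to the requested censored fraction.  Units: intensities in arbitrary
    fluorescence units, time in months.
    """

    n_patients: int
    group_probs: Mapping[str, float]
    her2_median: Mapping[str, float]
    her2_log_sigma: Mapping[str, float]
    emt_logit_mu: Mapping[str, float]
    emt_logit_sigma: Mapping[str, float]
    coupling: float  # target Spearman correlation HER2 ~ EMT
    pfs_hazard: Mapping[str, float]  # events per month
    censoring_fraction: float
    ctc_count_mean: float = 9.0  # of the shifted (count - 1) part, see draw
    ctc_count_dispersion: float = 1.5
    cutoff: int = 56
    unsampled_fraction_a: float = 0.0  # group-A patients without CTC data

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        probs = [self.group_probs.get(g, 0.0) for g in GROUPS]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError(
                f"group probabilities must be >= 0 and sum to 1, got {probs}"
            )
        if not -1.0 <= self.coupling <= 1.0:
            raise ValidationError(
                f"coupling must be in [-1, 1], got {self.coupling}"
            )
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValidationError("censoring_fraction must be in [0, 1)")
        if not 0.0 <= self.unsampled_fraction_a <= 1.0:
            raise ValidationError("unsampled_fraction_a must be in [0, 1]")
        for g in GROUPS:
            if self.pfs_hazard[g] <= 0:
                raise ValidationError(f"hazard for group {g} must be > 0")
            if self.her2_log_sigma[g] <= 0 or self.emt_logit_sigma[g] <= 0:
                raise ValidationError(f"scales for group {g} must be > 0")


def default_cohort_spec(n_patients: int = 27) -> CohortSpec:
    """Cohort conditions mirroring the 27-patient study.

    Group weights 13:8:6; HER2 intensity medians set so group B sits well
    above the 56 cutoff and group C below it; EMT logit-normal medians at
    the observed group medians (0.18 / 0.175 / 0.15); coupling at the
    observed Spearman 0.765; PFS hazards matching medians of 15.7 and 7.0
    months for A and B, with a low group-C hazard whose median is beyond
    the follow-up window ("not reached").
    """
    logit = lambda p: float(np.log(p / (1 - p)))
    ln2 = float(np.log(2.0))
    return CohortSpec(
        n_patients=n_patients,
        group_probs={"A": 13 / 27, "B": 8 / 27, "C": 6 / 27},
        her2_median={"A": 100.0, "B": 120.0, "C": 43.0},
        her2_log_sigma={"A": 0.55, "B": 0.40, "C": 0.25},
        emt_logit_mu={
            "A": logit(0.18), "B": logit(0.175), "C": logit(0.15)
        },
        emt_logit_sigma={"A": 0.20, "B": 0.22, "C": 0.10},
        coupling=0.765,
        pfs_hazard={"A": ln2 / 15.7, "B": ln2 / 7.0, "C": ln2 / 40.0},
        censoring_fraction=0.25,
        unsampled_fraction_a=4 / 13,
    )


def _censoring_window(hazard: float, target_fraction: float) -> float:
    """Window W such that C ~ U(0, W) censors an exponential(hazard) PFS
    with probability ``target_fraction``:  P(T > C) = (1 - e^{-hW})/(hW)."""
    frac = lambda w: (1.0 - np.exp(-hazard * w)) / (hazard * w)
    lo, hi = 1e-9, 1.0
    while frac(hi) > target_fraction:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - target_fraction ~ 0
            return hi
    return float(optimize.brentq(lambda w: frac(w) - target_fraction, lo, hi))


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula parameter reproducing a target Spearman correlation
    (exact for bivariate normal: r = 2 sin(pi * rho_s / 6))."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def _truncated_lognorm_ppf(
    u: np.ndarray, median: float, sigma: float,
    lower: float | None, upper: float | None,
) -> np.ndarray:
    dist = stats.lognorm(s=sigma, scale=median)
    lo = dist.cdf(lower) if lower is not None else 0.0
    hi = dist.cdf(upper) if upper is not None else 1.0
    return dist.ppf(lo + u * (hi - lo))


def simulate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Simulate a cohort table, one row per patient.

    Columns: patient_id, group (ground truth), tissue_her2, ctc_count,
    ctc_her2_intensity, ctc_her2_status, emt_index, pfs_months, pfs_event,
    her2_targeted_therapy, a_prime.  Group A patients are tissue-positive
    (and receive targeted therapy); groups B and C are tissue-negative.  A
    fraction of group-A patients carries no CTC measurement (columns NaN),
    mirroring patients sampled after therapy start.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_patients
    probs = np.array([spec.group_probs.get(g, 0.0) for g in GROUPS])
    groups = rng.choice(GROUPS, size=n, p=probs)

    # Gaussian copula: z1 drives HER2 intensity, z2 the EMT-index
    r = spearman_to_pearson(spec.coupling)
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    u1 = stats.norm.cdf(z1)

    her2 = np.empty(n)
    emt = np.empty(n)
    pfs_t = np.empty(n)
    for g in GROUPS:
        mask = groups == g
        m = int(mask.sum())
        if m == 0:
            continue
        lower = float(spec.cutoff) if g == "B" else None
        upper = float(spec.cutoff) if g == "C" else None
        her2[mask] = _truncated_lognorm_ppf(
            u1[mask], spec.her2_median[g], spec.her2_log_sigma[g],
            lower, upper,
        )
        emt[mask] = 1.0 / (1.0 + np.exp(
            -(spec.emt_logit_mu[g] + spec.emt_logit_sigma[g] * z2[mask])
        ))
        pfs_t[mask] = rng.exponential(1.0 / spec.pfs_hazard[g], size=m)

    # shifted negative binomial CTC count, support >= 1
    k = spec.ctc_count_dispersion
    mean_extra = max(spec.ctc_count_mean - 1.0, 1e-9)
    p_nb = k / (k + mean_extra)
    counts = 1 + rng.negative_binomial(k, p_nb, size=n)

    if spec.censoring_fraction > 0:
        observed = np.empty(n)
        event = np.empty(n, dtype=bool)
        for g in GROUPS:
            mask = groups == g
            if not mask.any():
                continue
            window = _censoring_window(
                spec.pfs_hazard[g], spec.censoring_fraction
            )
            cens = rng.uniform(0.0, window, size=int(mask.sum()))
            observed[mask] = np.minimum(pfs_t[mask], cens)
            event[mask] = pfs_t[mask] <= cens
    else:
        observed = pfs_t
        event = np.ones(n, dtype=bool)

    unsampled = (groups == "A") & (
        rng.random(n) < spec.unsampled_fraction_a
    )

    status = np.array(
        [classify_her2(x, spec.cutoff) for x in her2], dtype=object
    )
    frame = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "group": groups,
            "tissue_her2": np.where(groups == "A", "positive", "negative"),
            "ctc_count": counts.astype(float),
            "ctc_her2_intensity": her2,
            "ctc_her2_status": status,
            "emt_index": emt,
            "pfs_months": observed,
            "pfs_event": event,
            "her2_targeted_therapy": groups == "A",
            "a_prime": (groups == "A") & ~unsampled,
        }
    )
    ctc_cols = ["ctc_count", "ctc_her2_intensity", "emt_index"]
    frame.loc[unsampled, ctc_cols] = np.nan
    frame.loc[unsampled, "ctc_her2_status"] = None
    return frame


# --------------------------------------------------------------------------
# mutation matrices
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationModel:
    """Independent Bernoulli mutation calls.

    ``group_gene_probs[group][gene]`` is the per-sample mutation probability
    for CTC samples; tissue samples multiply it by
    ``source_modifier['tissue']`` (products above 1 clip with a warning).
    """

    genes: tuple[str, ...]
    group_gene_probs: Mapping[str, Mapping[str, float]]
    source_modifier: Mapping[str, float] = field(
        default_factory=lambda: {"CTC": 1.0, "tissue": 1.0}
    )

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("gene list must be non-empty")
        for g, probs in self.group_gene_probs.items():
            for gene in self.genes:
                p = probs.get(gene, 0.0)
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(
                        f"probability for {gene}/{g} must be in [0,1], got {p}"
                    )
        for src, m in self.source_modifier.items():
            if m <= 0:
                raise ValidationError(f"modifier for {src!r} must be > 0")

    def probability(self, gene: str, group: str, source: str) -> float:
        if group not in self.group_gene_probs:
            raise ValidationError(f"unknown group {group!r}")
        if source not in self.source_modifier:
            raise ValidationError(f"unknown source {source!r}")
        p = self.group_gene_probs[group].get(gene, 0.0)
        p_mod = p * self.source_modifier[source]
        if p_mod > 1.0:
            warnings.warn(
                f"modified probability {p_mod:.3f} for {gene}/{group}/"
                f"{source} clipped to 1",
                stacklevel=2,
            )
            p_mod = 1.0
        return p_mod


# Gene compartments echoing the observed three-group Venn structure:
# 6 genes mutated in all three groups, 5 shared by A and B only,
# 9 private to A, 5 private to B.
_SHARED_ALL = ("PBRM1", "ATM", "NF1", "NOTCH1", "ERBB2", "PIK3CA")
_SHARED_AB = ("MTOR", "ESR1", "GNAS", "ARID1A", "RAF1")
_A_ONLY = (
    "PDGFRB", "CDH1", "PTPN11", "MET", "ALK",
    "FGFR2", "RB1", "CCNE1", "BCL2",
)
_B_ONLY = ("TP53", "THBS1", "CCND1", "CDK6", "MLH1")


def default_mutation_model() -> MutationModel:
    """Rates chosen so per-sample mutated-gene counts center near medians
    7 / 6.5 / 4 for groups A / B / C, with tissue samples slightly sparser
    than CTCs."""
    genes = _SHARED_ALL + _SHARED_AB + _A_ONLY + _B_ONLY
    probs: dict[str, dict[str, float]] = {g: {} for g in GROUPS}
    for gene in genes:
        in_a = gene not in _B_ONLY
        in_b = gene not in _A_ONLY
        in_c = gene in _SHARED_ALL
        probs["A"][gene] = 0.35 if in_a else 0.0
        probs["B"][gene] = 0.40 if in_b else 0.0
        probs["C"][gene] = 0.65 if in_c else 0.0
    return MutationModel(
        genes=genes,
        group_gene_probs=probs,
        source_modifier={"CTC": 1.0, "tissue": 0.85},
    )


def simulate_mutation_matrix(
    model: MutationModel, samples: pd.DataFrame, seed: int
):
    """Draw a binary gene x sample matrix for the given sample sheet.

    ``samples`` needs columns ``sample``, ``patient_id``, ``group``,
    ``source``.  Returns a :class:`ctcflow.landscape.MutationMatrix`.
    """
    from ctcflow.landscape import MutationMatrix

    required = {"sample", "patient_id", "group", "source"}
    if not required.issubset(samples.columns):
        raise ValidationError(
            f"sample sheet needs columns {sorted(required)}"
        )
    rng = np.random.default_rng(seed)
    calls = np.zeros((len(model.genes), len(samples)), dtype=int)
    for j, row in enumerate(samples.itertuples(index=False)):
        p = np.array(
            [model.probability(g, row.group, row.source) for g in model.genes]
        )
        calls[:, j] = rng.random(len(model.genes)) < p
    matrix = pd.DataFrame(
        calls, index=list(model.genes), columns=list(samples["sample"])
    )
    meta = samples.set_index("sample")[["patient_id", "group", "source"]]
    return MutationMatrix(calls=matrix, meta=meta)
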