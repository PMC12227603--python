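"""Spillover compensation and the four-round CTC sort cascade.

Events are rows of a pandas DataFrame with one nonnegative intensity column
per channel (see :mod:`ctcflow.channels`); the boolean ``compensated`` flag
travels in ``DataFrame.attrs``.

Compensation follows the linear mixing convention ``measured = true @ S``
where ``S[j, k]`` is the fraction of channel-j true signal read in channel k
(diagonal 1).  Correction solves the linear system rather than forming an
explicit inverse.

A CTC is defined operationally as a nucleated (Hoechst-positive),
cytokeratin-positive, CD45-negative event that survives every round of the
sort cascade.  The physical re-collection steps between sorts are modeled as
an optional per-round Bernoulli carryover loss (default 0: lossless).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ctcflow.channels import CHANNELS, validate_channel
from ctcflow.errors import (
    DegenerateControlError,
    NoCTCsError,
    SingularSpilloverError,
    ValidationError,
)

__all__ = [
    "GatePredicate",
    "GateSpec",
    "SortCascadeResult",
    "SpilloverMatrix",
    "compensate",
    "default_ctc_cascade",
    "enumerate_ctcs",
    "estimate_spillover",
    "run_sort_cascade",
    "suggest_cutoff",
    "summarize_patient",
]

#: condition-number ceiling above which compensation refuses to proceed
MAX_CONDITION_NUMBER = 1e8


@dataclass(frozen=True)
class SpilloverMatrix:
    """Square spillover matrix over the five channels.

    ``values[j, k]`` is the fraction of channel-j true signal that bleeds
    into measured channel k.  Diagonal entries are 1 by construction.
    """

    values: np.ndarray
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.channels)
        if v.shape != (n, n):
            raise ValidationError(f"spillover must be {n}x{n}, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("spillover entries must be finite")
        if np.any(v < 0):
            raise ValidationError("spillover entries must be >= 0")
        if not np.allclose(np.diag(v), 1.0):
            raise ValidationError("spillover diagonal must be 1")

    @classmethod
    def identity(cls) -> "SpilloverMatrix":
        return cls(np.eye(len(CHANNELS)))

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.channels), columns=list(self.channels)
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="channel")

    @classmethod
    def from_csv(cls, path) -> "SpilloverMatrix":
        frame = pd.read_csv(path, index_col=0)
        if list(frame.columns) != list(CHANNELS) or list(frame.index) != list(
            CHANNELS
        ):
            raise ValidationError(
                f"spillover CSV must be labeled by {CHANNELS} on both axes"
            )
        return cls(frame.to_numpy(dtype=float))


@dataclass(frozen=True)
class GatePredicate:
    """One gate: keep events whose ``channel`` intensity satisfies
    ``comparator cutoff``."""

    channel: str
    comparator: str  # one of > >= < <=
    cutoff: float

    _OPS = {
        ">": np.greater,
        ">=": np.greater_equal,
        "<": np.less,
        "<=": np.less_equal,
    }

    def __post_init__(self) -> None:
        validate_channel(self.channel)
        if self.comparator not in self._OPS:
            raise ValidationError(
                f"comparator must be one of {sorted(self._OPS)}, "
                f"got {self.comparator!r}"
            )
        if not np.isfinite(self.cutoff):
            raise ValidationError("gate cutoff must be finite")

    def mask(self, events: pd.DataFrame) -> np.ndarray:
        if self.channel not in events.columns:
            raise ValidationError(
                f"events lack channel {self.channel!r}"
            )
        return self._OPS[self.comparator](
            events[self.channel].to_numpy(), self.cutoff
        )


@dataclass(frozen=True)
class GateSpec:
    """One sorting round: the conjunction of an ordered list of predicates."""

    predicates: tuple[GatePredicate, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.predicates:
            raise ValidationError("a gate round needs >= 1 predicate")
        object.__setattr__(self, "predicates", tuple(self.predicates))

    def mask(self, events: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(events), dtype=bool)
        for pred in self.predicates:
            out &= pred.mask(events)
        return out


@dataclass
class SortCascadeResult:
    """Per-round retained counts and the final CTC event subset."""

    round_counts: list[int]
    round_names: list[str]
    events: pd.DataFrame
    carryover_losses: list[int] = field(default_factory=list)

    @property
    def input_count(self) -> int:
        return self.round_counts[0] if self.round_counts else 0

    @property
    def final_count(self) -> int:
        return len(self.events)

    def to_dict(self) -> dict:
        return {
            "round_names": self.round_names,
            "round_counts": self.round_counts,
            "carryover_losses": self.carryover_losses,
            "final_count": self.final_count,
        }


def estimate_spillover(
    controls: Mapping[str, pd.DataFrame],
    baselines: Mapping[str, float],
    min_events: int = 50,
) -> SpilloverMatrix:
    """Estimate the spillover matrix from single-stain controls.

    ``controls[j]`` is an event table stained only on channel ``j``.  The
    off-diagonal entry (j, k) is the ratio of median off-channel signal above
    baseline to median on-channel signal above baseline — medians, not means,
    so a handful of aberrant events cannot skew the estimate.  Negative
    ratios (off-channel median below baseline, pure noise) clip to 0.
    """
    missing = [c for c in CHANNELS if c not in controls]
    if missing:
        raise ValidationError(f"missing single-stain controls for {missing}")
    S = np.eye(len(CHANNELS))
    for j, chan_j in enumerate(CHANNELS):
        table = controls[chan_j]
        if len(table) < min_events:
            raise ValidationError(
                f"control for {chan_j!r} has {len(table)} events; "
                f"need >= {min_events}"
            )
        medians = table[list(CHANNELS)].median()
        on = medians[chan_j] - baselines[chan_j]
        if on <= 0:
            raise DegenerateControlError(
                f"control for {chan_j!r}: on-channel median "
                f"{medians[chan_j]:.3g} does not exceed baseline "
                f"{baselines[chan_j]:.3g}"
            )
        for k, chan_k in enumerate(CHANNELS):
            if k == j:
                continue
            S[j, k] = max(0.0, (medians[chan_k] - baselines[chan_k]) / on)
    return SpilloverMatrix(S)


def compensate(
    events: pd.DataFrame,
    spillover: SpilloverMatrix,
    baselines: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Undo spillover: solve ``c @ S = m`` for each measured row ``m``.

    With ``baselines`` given, the autofluorescence floor is subtracted before
    unmixing and added back after, so only the stain component is unmixed.
    The system is solved directly (no explicit inverse); an ill-conditioned
    matrix raises :class:`SingularSpilloverError`.
    """
    if events.attrs.get("compensated", False):
        raise ValidationError("events are already compensated")
    S = spillover.values
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > MAX_CONDITION_NUMBER:
        raise SingularSpilloverError(
            f"spillover matrix condition number {cond:.3g} exceeds "
            f"{MAX_CONDITION_NUMBER:.0e}"
        )
    m = events[list(CHANNELS)].to_numpy(dtype=float)
    if baselines is not None:
        base = np.array([baselines[c] for c in CHANNELS])
        m = m - base
    # c @ S = m  <=>  S.T @ c.T = m.T
    c = np.linalg.solve(S.T, m.T).T
    if baselines is not None:
        c = c + base
    out = events.copy()
    out[list(CHANNELS)] = c
    out.attrs["compensated"] = True
    return out


def run_sort_cascade(
    events: pd.DataFrame,
    cascade: Sequence[GateSpec],
    carryover_loss: float | Sequence[float] = 0.0,
    rng: np.random.Generator | None = None,
) -> SortCascadeResult:
    """Apply the sorting rounds sequentially, recording retained counts.

    Each round keeps the survivors of the previous round that satisfy all of
    its predicates; counts are therefore weakly decreasing.  ``carryover_loss``
    models imperfect physical re-collection between rounds as an independent
    per-event Bernoulli drop (default 0).
    """
    if not cascade:
        raise ValidationError("cascade must have >= 1 round")
    if not events.attrs.get("compensated", False):
        warnings.warn(
            "running the sort cascade on uncompensated events", stacklevel=2
        )
    losses = (
        [float(carryover_loss)] * len(cascade)
        if np.isscalar(carryover_loss)
        else [float(x) for x in carryover_loss]
    )
    if len(losses) != len(cascade):
        raise ValidationError(
            f"need one carryover loss per round, got {len(losses)} "
            f"for {len(cascade)} rounds"
        )
    if any(loss < 0 or loss >= 1 for loss in losses):
        raise ValidationError("carryover losses must be in [0, 1)")
    if any(loss > 0 for loss in losses) and rng is None:
        raise ValidationError("carryover loss > 0 requires an rng")

    current = events
    counts = [len(events)]
    names = []
    dropped = []
    for gate, loss in zip(cascade, losses):
        kept = current[gate.mask(current)]
        n_lost = 0
        if loss > 0 and len(kept) > 0:
            survive = rng.random(len(kept)) >= loss
            n_lost = int((~survive).sum())
            kept = kept[survive]
        dropped.append(n_lost)
        counts.append(len(kept))
        names.append(gate.name or f"round_{len(names) + 1}")
        current = kept
    result = SortCascadeResult(
        round_counts=counts,
        round_names=["input"] + names,
        events=current,
        carryover_losses=dropped,
    )
    result.events.attrs.update(events.attrs)
    return result


def enumerate_ctcs(result: SortCascadeResult) -> int:
    """Number of events in the final retained set."""
    return result.final_count


@dataclass(frozen=True)
class PatientSignals:
    """Per-patient mean fluorescence over the final CTC set."""

    mean_her2: float
    mean_ck: float
    mean_vim: float
    n_ctcs: int


def summarize_patient(ctc_events: pd.DataFrame) -> PatientSignals:
    """Arithmetic channel means over the final CTC events.

    Raises :class:`NoCTCsError` on an empty set — a real biological outcome
    that callers must handle explicitly, not a data error.
    """
    if len(ctc_events) == 0:
        raise NoCTCsError("no CTC events to summarize")
    return PatientSignals(
        mean_her2=float(ctc_events["her2"].mean()),
        mean_ck=float(ctc_events["ck"].mean()),
        mean_vim=float(ctc_events["vim"].mean()),
        n_ctcs=len(ctc_events),
    )


def suggest_cutoff(values: np.ndarray, random_state: int = 0) -> float:
    """Midpoint gate between the two modes of a bimodal intensity channel.

    Fits a two-component Gaussian mixture on log10 intensities and returns
    the midpoint between the component means, back on the intensity scale.
    Used to place "positive"/"negative" gates when only qualitative gate
    definitions are available.
    """
    from sklearn.mixture import GaussianMixture

    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    if len(v) < 10:
        raise ValidationError("need >= 10 positive values to place a gate")
    gm = GaussianMixture(n_components=2, random_state=random_state)
    gm.fit(np.log10(v).reshape(-1, 1))
    lo, hi = np.sort(gm.means_.ravel())
    return float(10 ** ((lo + hi) / 2.0))


def default_ctc_cascade(
    ck_cut: float, cd45_cut: float, hoechst_cut: float
) -> list[GateSpec]:
    """The four-round sort: CK+ enrichment twice, then two rounds of
    nucleated CK+ CD45- selection."""
    ck_pos = GatePredicate("ck", ">", ck_cut)
    full = (
        GatePredicate("hoechst", ">", hoechst_cut),
        ck_pos,
        GatePredicate("cd45", "<", cd45_cut),
    )
    return [
        GateSpec((ck_pos,), name="sort1_ck"),
        GateSpec((ck_pos,), name="sort2_ck"),
        GateSpec(full, name="sort3_nuc_ck_cd45"),
        GateSpec(full, name="sort4_nuc_ck_cd45"),
    ]
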