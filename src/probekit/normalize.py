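"""The 2-8% box-plot normalization of chemical probing reactivities.

The rule, applied to the measured reactivities of one profile:

1. select the top 10% most reactive positions (``n_selected = ceil(0.10 N)``);
2. exclude the top 20% of that selection as outliers
   (``n_excluded = ceil(0.20 n_selected)``);
3. the divisor is the mean of the remaining ~8% most reactive values;
4. every measured value is divided by it, then clamped to [0, 1].

Missing positions stay missing.  In nucleotide-specific mode (DMS and CMCT
probes modify only a subset of bases) the divisor is computed from the
susceptible letters only — A/C for DMS, G/U for CMCT — but all measured
positions are still divided and clamped, so the full profile remains
displayable.

Ceiling is used for both counts so the rule stays defined at small N; the
smallest usable N under this rounding is 11.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    NonPositiveFactorError,
    ReconciliationError,
    StateError,
    TooFewValuesError,
)
from .probing_io import ReactivityProfile

#: Letters expected to react with each probe.  SHAPE acylates the 2'-OH of
#: every nucleotide; DMS methylates A(N1)/C(N3); CMCT modifies G(N1)/U(N3).
SUSCEPTIBILITY: dict[str, frozenset[str]] = {
    "SHAPE": frozenset("ACGU"),
    "DMS": frozenset("AC"),
    "CMCT": frozenset("GU"),
}

MIN_USABLE_N = 11


@dataclass
class NormalizationResult:
    """A normalized profile plus the bookkeeping of how its divisor was built."""

    profile: ReactivityProfile
    factor: float
    n_selected: int
    n_excluded: int
    subset: str  # "all measured" or e.g. "measured at DMS-susceptible letters (A/C)"


def selection_counts(n: int) -> tuple[int, int]:
    """Counts of selected and excluded top reactivities for N measured values.

    Returns ``(n_selected, n_excluded)`` with ``n_selected = ceil(N/10)`` and
    ``n_excluded = ceil(n_selected/5)``.  Raises :class:`TooFewValuesError`
    when no value would remain to average (N < 11 under this rounding).
    """
    if n < 1:
        raise TooFewValuesError("need at least one measured value")
    n_selected = -(-n // 10)
    n_excluded = -(-n_selected // 5)
    if n_selected - n_excluded < 1:
        raise TooFewValuesError(
            f"{n} measured values leave no position to average after selecting "
            f"{n_selected} and excluding {n_excluded}; the rule needs at least "
            f"{MIN_USABLE_N} values"
        )
    return n_selected, n_excluded


def normalization_factor(values) -> float:
    """Divisor for a collection of measured raw reactivities.

    Ranks the values in descending order (stable: ties keep input order),
    drops the ``n_excluded`` highest, and averages ranks
    ``n_excluded+1 .. n_selected``.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1:
        raise ValueError("values must be one-dimensional")
    n_selected, n_excluded = selection_counts(vals.size)
    # argsort of -vals is stable, so equal values keep ascending-position order
    order = np.argsort(-vals, kind="stable")
    window = vals[order[n_excluded:n_selected]]
    factor = float(window.mean())
    if factor <= 0:
        raise NonPositiveFactorError(
            f"normalization divisor is {factor:.4g}; the top reactivities are "
            "non-positive, so the profile cannot be scaled"
        )
    return factor


def normalize_profile(
    profile: ReactivityProfile, nucleotide_specific: bool = False
) -> NormalizationResult:
    """Apply the 2-8% normalization to a raw profile.

    With ``nucleotide_specific=True`` the divisor is computed only from
    measured values at letters susceptible to ``profile.probe``; every
    measured position is divided and clamped regardless of subset membership.
    """
    if profile.normalized:
        raise StateError("profile is already normalized")
    letters = SUSCEPTIBILITY[profile.probe]
    if nucleotide_specific:
        subset_mask = profile.measured & np.array(
            [c in letters for c in profile.sequence.residues]
        )
        subset_desc = (
            f"measured at {profile.probe}-susceptible letters "
            f"({'/'.join(sorted(letters))})"
        )
    else:
        subset_mask = profile.measured
        subset_desc = "all measured"

    subset_vals = profile.values[subset_mask]
    try:
        n_selected, n_excluded = selection_counts(int(subset_mask.sum()))
        factor = normalization_factor(subset_vals)
    except (TooFewValuesError, NonPositiveFactorError) as exc:
        raise type(exc)(f"{exc} (subset: {subset_desc})") from exc

    values = profile.values.copy()
    values[profile.measured] = np.clip(values[profile.measured] / factor, 0.0, 1.0)
    out = ReactivityProfile(
        sequence=profile.sequence,
        values=values,
        measured=profile.measured,
        probe=profile.probe,
        normalized=True,
        origin=profile.origin,
    )
    return NormalizationResult(
        profile=out, factor=factor, n_selected=n_selected,
        n_excluded=n_excluded, subset=subset_desc,
    )


def average_profiles(profiles) -> ReactivityProfile:
    """Average two or more normalized replicate profiles position-wise.

    Each position is the arithmetic mean over the replicates in which it was
    measured; it is missing only when missing in every replicate.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to average")
    first = profiles[0]
    for p in profiles:
        if not p.normalized:
            raise StateError("replicates must be normalized before averaging")
        if p.sequence.residues != first.sequence.residues:
            raise ReconciliationError("replicate sequences differ; cannot average")
    stack = np.vstack([p.values for p in profiles])
    counts = np.vstack([p.measured for p in profiles]).sum(axis=0)
    measured = counts > 0
    values = np.full(len(first), np.nan)
    with np.errstate(invalid="ignore"):
        values[measured] = np.nansum(stack, axis=0)[measured] / counts[measured]
    return ReactivityProfile(
        sequence=first.sequence,
        values=values,
        measured=measured,
        probe=first.probe,
        normalized=True,
        origin=" + ".join(p.origin for p in profiles if p.origin) or first.origin,
    )
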