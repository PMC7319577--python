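"""Input/output for probing data: sequences, QuShape tables, reactivity files.

Conventions used throughout the package:

* positions are 1-based and inclusive;
* a missing (no readout) position is a distinct *state*, stored as NaN plus a
  boolean mask — the sentinels ``-999`` (reactivity files) and ``-1``
  (tables, B-factors, color maps) exist only at serialization boundaries;
* reactivity files use the two-column dialect accepted by RNAfold's and
  ShapeKnots' SHAPE options: ``<position> <value>``, with ``-999`` marking
  positions of unknown reactivity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    EmptyRoiError,
    FormatError,
    InvalidSequenceError,
    ReconciliationError,
    StateError,
)

VALID_LETTERS = frozenset("ACGU")

#: QuShape's background-subtracted raw signal column, used when the caller
#: does not name a reactivity column explicitly.
DEFAULT_QUSHAPE_COLUMN = "areaDiff"

PROBES = ("SHAPE", "DMS", "CMCT")


@dataclass(frozen=True)
class RNASequence:
    """An RNA sequence over {A, C, G, U} with 1-based positions."""

    identifier: str
    residues: str

    def __post_init__(self):
        if len(self.residues) == 0:
            raise InvalidSequenceError("sequence is empty")
        bad = set(self.residues) - VALID_LETTERS
        if bad:
            pos = next(i + 1 for i, c in enumerate(self.residues) if c in bad)
            raise InvalidSequenceError(
                f"invalid residue {self.residues[pos - 1]!r} at position {pos}",
                position=pos,
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, idx):
        return self.residues[idx]


def canonicalize_sequence(raw: str, identifier: str = "seq") -> RNASequence:
    """Canonicalize user sequence input (bare text or FASTA).

    FASTA header/comment lines are dropped, whitespace is stripped, letters
    are upper-cased, and DNA-style T is rewritten to U.  Any other character
    raises :class:`InvalidSequenceError` naming its 1-based position in the
    canonicalized sequence.
    """
    lines = [ln.strip() for ln in raw.splitlines()]
    body = "".join(ln for ln in lines if ln and not ln.startswith((">", ";")))
    body = "".join(body.split())
    if not body:
        raise InvalidSequenceError("sequence is empty after removing headers/whitespace")
    out = body.upper().replace("T", "U")
    for i, c in enumerate(out):
        if c not in VALID_LETTERS:
            raise InvalidSequenceError(
                f"invalid character {body[i]!r} at position {i + 1}: "
                "sequence must contain only A, C, G, U (T is accepted and read as U)",
                position=i + 1,
            )
    return RNASequence(identifier=identifier, residues=out)


@dataclass
class ReactivityProfile:
    """Per-nucleotide reactivities of one probed RNA.

    ``values`` holds NaN at missing positions; ``measured`` is the boolean
    state mask.  ``normalized`` records whether the 2-8% normalization (or an
    upstream equivalent) has been applied, in which case every measured value
    lies in [0, 1].
    """

    sequence: RNASequence
    values: np.ndarray
    measured: np.ndarray
    probe: str = "SHAPE"
    normalized: bool = False
    origin: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).copy()
        self.measured = np.asarray(self.measured, dtype=bool).copy()
        n = len(self.sequence)
        if self.values.shape != (n,) or self.measured.shape != (n,):
            raise ValueError(
                f"values/state length ({self.values.shape[0]}/{self.measured.shape[0]}) "
                f"does not match sequence length ({n})"
            )
        if self.probe not in PROBES:
            raise ValueError(f"unknown probe {self.probe!r}; expected one of {PROBES}")
        self.values[~self.measured] = np.nan
        if self.normalized:
            mv = self.values[self.measured]
            if mv.size and (np.nanmin(mv) < 0 or np.nanmax(mv) > 1):
                raise ValueError("normalized profile has measured values outside [0, 1]")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_measured(self) -> int:
        return int(self.measured.sum())

    def measured_values(self) -> np.ndarray:
        return self.values[self.measured]

    def display_values(self, sentinel: float = -1.0) -> np.ndarray:
        """Values with missing positions replaced by the display sentinel."""
        out = self.values.copy()
        out[~self.measured] = sentinel
        return out


@dataclass(frozen=True)
class RegionOfInterest:
    """Counts of positions discarded from the 5' and 3' ends (e.g. a cassette)."""

    trim5: int = 0
    trim3: int = 0

    def __post_init__(self):
        if self.trim5 < 0 or self.trim3 < 0:
            raise ValueError("trims must be non-negative")

    def validate(self, length: int) -> None:
        if self.trim5 + self.trim3 >= length:
            raise EmptyRoiError(
                f"trims ({self.trim5} + {self.trim3}) remove all {length} positions"
            )


@dataclass
class MismatchReport:
    """Outcome of comparing a profile's sequence against a reference."""

    mismatches: list = field(default_factory=list)  # (position, profile_letter, reference_letter)
    length_difference: int = 0  # len(profile) - len(reference)

    @property
    def empty(self) -> bool:
        return not self.mismatches and self.length_difference == 0

    def describe(self) -> str:
        parts = []
        if self.length_difference:
            parts.append(f"length differs by {self.length_difference:+d}")
        for pos, a, b in self.mismatches[:20]:
            parts.append(f"position {pos}: profile has {a}, reference has {b}")
        if len(self.mismatches) > 20:
            parts.append(f"... and {len(self.mismatches) - 20} more mismatches")
        return "; ".join(parts) if parts else "sequences identical"


def parse_qushape(
    text: str,
    reactivity_column: str = DEFAULT_QUSHAPE_COLUMN,
    probe: str = "SHAPE",
    origin: str = "",
) -> ReactivityProfile:
    """Parse a QuShape tab-separated export into a raw (non-normalized) profile.

    The sequence is read from the ``seqRNA`` column; the reactivity comes
    from ``reactivity_column``.  Rows whose reactivity cell is empty or
    non-numeric become *missing* positions.  Extra columns are ignored.
    """
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse QuShape file: {exc}") from exc
    if df.empty:
        raise FormatError("QuShape file contains no data rows")
    for col in ("seqRNA", reactivity_column):
        if col not in df.columns:
            raise FormatError(f"QuShape file lacks required column {col!r}")
    if "seqNum" in df.columns:
        nums = pd.to_numeric(df["seqNum"], errors="coerce")
        if nums.isna().any():
            row = int(nums.isna().idxmax()) + 2  # header is line 1
            raise FormatError("non-numeric seqNum value", line=row)
        if nums.duplicated().any() or not nums.is_monotonic_increasing:
            raise FormatError("seqNum positions are duplicated or non-monotonic")

    letters = []
    for idx, cell in enumerate(df["seqRNA"]):
        letter = str(cell).strip().upper().replace("T", "U")
        if len(letter) != 1 or letter not in VALID_LETTERS:
            raise FormatError(
                f"invalid seqRNA entry {cell!r} in data row {idx + 1}", line=idx + 2
            )
        letters.append(letter)
    seq = RNASequence(identifier=origin or "qushape", residues="".join(letters))

    raw = pd.to_numeric(df[reactivity_column], errors="coerce").to_numpy(dtype=float)
    measured = ~np.isnan(raw)
    return ReactivityProfile(
        sequence=seq, values=raw, measured=measured, probe=probe,
        normalized=False, origin=origin,
    )


def reconcile(
    profile: ReactivityProfile, reference: RNASequence, strict: bool = False
) -> MismatchReport:
    """Compare a profile's sequence to the user reference, position by position.

    Returns a :class:`MismatchReport`; with ``strict=True`` a non-empty report
    raises :class:`ReconciliationError` instead of being returned.
    """
    report = MismatchReport()
    a, b = profile.sequence.residues, reference.residues
    report.length_difference = len(a) - len(b)
    for pos in range(1, min(len(a), len(b)) + 1):
        if a[pos - 1] != b[pos - 1]:
            report.mismatches.append((pos, a[pos - 1], b[pos - 1]))
    if strict and not report.empty:
        raise ReconciliationError(
            f"profile sequence disagrees with reference: {report.describe()}",
            report=report,
        )
    return report


def apply_roi(profile: ReactivityProfile, roi: RegionOfInterest) -> ReactivityProfile:
    """Trim a profile to its region of interest, renumbering from 1.

    The retained window is positions ``trim5+1 .. L-trim3`` of the input; the
    applied offset is recorded in the origin label so original coordinates
    stay recoverable.
    """
    n = len(profile)
    roi.validate(n)
    if roi.trim5 == 0 and roi.trim3 == 0:
        return replace(profile, origin=profile.origin)
    sl = slice(roi.trim5, n - roi.trim3)
    seq = RNASequence(profile.sequence.identifier, profile.sequence.residues[sl])
    origin = f"{profile.origin}[roi:+{roi.trim5},-{roi.trim3}]" if profile.origin else (
        f"[roi:+{roi.trim5},-{roi.trim3}]"
    )
    return ReactivityProfile(
        sequence=seq,
        values=profile.values[sl],
        measured=profile.measured[sl],
        probe=profile.probe,
        normalized=profile.normalized,
        origin=origin,
    )


MISSING_SENTINEL = -999.0


def read_reactivity_file(
    text: str,
    sequence: RNASequence,
    probe: str = "SHAPE",
    origin: str = "",
) -> ReactivityProfile:
    """Read a two-column (position, value) reactivity file.

    The file carries values only; the sequence is supplied by the caller.
    ``-999`` and absent positions both map to the missing state.  The result
    is flagged normalized (this dialect holds pre-normalized values).
    """
    n = len(sequence)
    values = np.full(n, np.nan)
    measured = np.zeros(n, dtype=bool)
    seen: set[int] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(
                f"expected two whitespace-separated fields, got {len(fields)}", line=lineno
            )
        try:
            pos = int(fields[0])
            val = float(fields[1])
        except ValueError as exc:
            raise FormatError(f"non-numeric field in {line!r}", line=lineno) from exc
        if pos in seen:
            raise FormatError(f"duplicate position {pos}", line=lineno)
        seen.add(pos)
        if not 1 <= pos <= n:
            raise FormatError(
                f"position {pos} outside sequence of length {n}", line=lineno
            )
        if val == MISSING_SENTINEL:
            continue
        values[pos - 1] = val
        measured[pos - 1] = True
    return ReactivityProfile(
        sequence=sequence, values=values, measured=measured,
        probe=probe, normalized=True, origin=origin,
    )


def write_reactivity_file(profile: ReactivityProfile) -> str:
    """Serialize a normalized profile to the two-column reactivity dialect.

    One line per position: the 1-based position and the value to 3 decimals;
    missing positions are written as ``-999``.
    """
    if not profile.normalized:
        raise StateError("reactivity files hold normalized values; normalize first")
    lines = []
    for i in range(len(profile)):
        if profile.measured[i]:
            lines.append(f"{i + 1} {profile.values[i]:.3f}")
        else:
            lines.append(f"{i + 1} -999")
    return "\n".join(lines) + "\n"


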