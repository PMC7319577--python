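"""Adapters around external secondary-structure prediction programs.

Each analysis mode maps to a fixed, ordered set of engines:

* SHAPE  — ViennaRNA ``RNAfold`` in SHAPE-reactivity mode, then RNAstructure
  ``ShapeKnots`` (pseudoknot-capable);
* DMS / CMCT — RNAstructure ``Fold`` with the matching probing option;
* PREDICT (sequence-only) — ``RNAfold``, ``Fold``, ``ProbKnot``,
  ``CentroidFold``, ``CONTRAfold``, ``IPknot``, ``LinearFold-C``,
  ``LinearFold-V``.

All tools run with their default settings; the reactivity-to-pseudo-energy
conversion happens inside the tools themselves.  A missing executable yields
a *skipped* prediction (with a logged warning), never a crash, so a run
degrades gracefully to whichever engines are installed.  In-process runner
callables (see :func:`probekit.synthetic.make_mock_engine`) stand in for
executables in tests.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

from .errors import ConfigurationError, DotBracketError
from .probing_io import RNASequence
from .structures import SecondaryStructure, parse_dotbracket

log = logging.getLogger(__name__)

MODES = ("SHAPE", "DMS", "CMCT", "PREDICT")

#: runner(sequence, reactivity_path) -> raw output text, or None = unavailable
Runner = Callable[[RNASequence, Optional[Path]], Optional[str]]


@dataclass(frozen=True)
class EngineSpec:
    """One external prediction method and how to invoke it."""

    name: str
    modes: frozenset
    accepts_reactivities: bool
    executable: str
    #: how the raw output encodes the structure: "vienna" (dot-bracket on
    #: stdout), "ct" (connectivity table file), or "dotbracket-line" (first
    #: dot-bracket-looking line of stdout)
    output_kind: str = "vienna"
    runner: Optional[Runner] = None

    def __post_init__(self):
        if not self.modes:
            raise ValueError("engine must support at least one mode")
        probing = self.modes & {"SHAPE", "DMS", "CMCT"}
        if probing and not self.accepts_reactivities:
            raise ValueError(
                f"{self.name}: probing-mode engines must accept reactivities"
            )


@dataclass
class Prediction:
    """Outcome of running one engine on one sequence."""

    engine: str
    structure: Optional[SecondaryStructure]
    raw_output: str = ""
    status: str = "ok"  # ok | skipped | failed
    message: str = ""


def _specs() -> dict[str, EngineSpec]:
    mk = EngineSpec
    return {
        s.name: s
        for s in [
            mk("RNAfold-SHAPE", frozenset({"SHAPE"}), True, "RNAfold", "vienna"),
            mk("ShapeKnots", frozenset({"SHAPE"}), True, "ShapeKnots", "ct"),
            mk("Fold-DMS", frozenset({"DMS"}), True, "Fold", "ct"),
            mk("Fold-CMCT", frozenset({"CMCT"}), True, "Fold", "ct"),
            mk("RNAfold", frozenset({"PREDICT"}), False, "RNAfold", "vienna"),
            mk("Fold", frozenset({"PREDICT"}), False, "Fold", "ct"),
            mk("ProbKnot", frozenset({"PREDICT"}), False, "ProbKnot", "ct"),
            mk("CentroidFold", frozenset({"PREDICT"}), False, "centroid_fold",
               "dotbracket-line"),
            mk("CONTRAfold", frozenset({"PREDICT"}), False, "contrafold",
               "dotbracket-line"),
            mk("IPknot", frozenset({"PREDICT"}), False, "ipknot", "dotbracket-line"),
            mk("LinearFold-C", frozenset({"PREDICT"}), False, "linearfold",
               "dotbracket-line"),
            mk("LinearFold-V", frozenset({"PREDICT"}), False, "linearfold",
               "dotbracket-line"),
        ]
    }


#: registry order per mode (the SHAPE list is RNAfold first, as displayed)
_MODE_ORDER = {
    "SHAPE": ["RNAfold-SHAPE", "ShapeKnots"],
    "DMS": ["Fold-DMS"],
    "CMCT": ["Fold-CMCT"],
    "PREDICT": [
        "RNAfold", "Fold", "ProbKnot", "CentroidFold",
        "CONTRAfold", "IPknot", "LinearFold-C", "LinearFold-V",
    ],
}


def build_registry(mode: str, engine_paths: dict[str, str] | None = None) -> list[EngineSpec]:
    """Ordered engine specs for an analysis mode.

    ``engine_paths`` maps engine names to explicit executable paths, replacing
    the default PATH lookup for those engines.
    """
    mode = mode.upper()
    if mode not in _MODE_ORDER:
        raise ConfigurationError(f"unknown mode {mode!r}; expected one of {MODES}")
    specs = _specs()
    out = []
    for name in _MODE_ORDER[mode]:
        spec = specs[name]
        if engine_paths and name in engine_paths:
            spec = EngineSpec(
                spec.name, spec.modes, spec.accepts_reactivities,
                engine_paths[name], spec.output_kind, spec.runner,
            )
        out.append(spec)
    return out


def _build_command(
    spec: EngineSpec, seq_path: Path, ct_path: Path, shape: Optional[Path]
) -> tuple[list[str], Optional[str]]:
    """argv and stdin text for one engine invocation (default settings)."""
    name, exe = spec.name, spec.executable
    if name in ("RNAfold", "RNAfold-SHAPE"):
        argv = [exe, "--noPS"]
        if shape is not None:
            argv.append(f"--shape={shape}")
        return argv, None  # sequence goes on stdin
    if name == "ShapeKnots":
        argv = [exe, str(seq_path), str(ct_path)]
        if shape is not None:
            argv += ["-sh", str(shape)]
        return argv, None
    if name in ("Fold", "Fold-DMS", "Fold-CMCT"):
        argv = [exe, str(seq_path), str(ct_path)]
        if name == "Fold-DMS" and shape is not None:
            argv += ["--DMS", str(shape)]
        elif name == "Fold-CMCT" and shape is not None:
            argv += ["--CMCT", str(shape)]
        return argv, None
    if name == "ProbKnot":
        return [exe, str(seq_path), str(ct_path), "--sequence"], None
    if name == "CentroidFold":
        return [exe, str(seq_path)], None
    if name == "CONTRAfold":
        return [exe, "predict", str(seq_path)], None
    if name == "IPknot":
        return [exe, str(seq_path)], None
    if name == "LinearFold-C":
        return [exe], "stdin-seq"
    if name == "LinearFold-V":
        return [exe, "-V"], "stdin-seq"
    raise ConfigurationError(f"no command template for engine {name!r}")


def parse_ct(text: str) -> SecondaryStructure:
    """Parse a connectivity-table (CT) file; first structure only."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DotBracketError("empty CT output")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise DotBracketError(f"malformed CT header: {lines[0]!r}") from exc
    pairs: set[tuple[int, int]] = set()
    for ln in lines[1 : n + 1]:
        fields = ln.split()
        if len(fields) < 5:
            raise DotBracketError(f"malformed CT row: {ln!r}")
        i, j = int(fields[0]), int(fields[4])
        if j > i:
            pairs.add((i, j))
    return SecondaryStructure(length=n, pairs=frozenset(pairs))


def _extract_structure(
    spec: EngineSpec, stdout: str, ct_path: Path, length: int
) -> SecondaryStructure:
    if spec.output_kind == "ct":
        return parse_ct(ct_path.read_text())
    if spec.output_kind == "vienna":
        # line 1: sequence, line 2: "<structure> ( energy)"
        lines = [ln for ln in stdout.splitlines() if ln.strip()]
        if len(lines) < 2:
            raise DotBracketError(f"unexpected output: {stdout[:200]!r}")
        return parse_dotbracket(lines[1].split()[0], length=length)
    # dotbracket-line: first stdout token that looks like a full-length
    # structure (a pure-letter token is a sequence echo, not a structure)
    allowed = set(".()[]{}<>") | set(
        "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
    )
    for ln in stdout.splitlines():
        for token in ln.split():
            if len(token) == length and set(token) <= allowed and not token.isalpha():
                return parse_dotbracket(token, length=length)
    raise DotBracketError(f"no dot-bracket of length {length} in output")


def run_engine(
    spec: EngineSpec,
    sequence: RNASequence,
    reactivities: Optional[Path] = None,
    workdir: Optional[Path] = None,
) -> Prediction:
    """Run one engine on a sequence, returning ok / skipped / failed.

    ``reactivities`` is a reactivity file path in the RNAfold/ShapeKnots
    dialect, passed only to engines that accept it.  Input files are never
    modified; intermediate files go to a temporary directory.
    """
    shape = Path(reactivities) if (reactivities and spec.accepts_reactivities) else None

    if spec.runner is not None:
        raw = spec.runner(sequence, shape)
        if raw is None:
            log.warning("engine %s unavailable; skipping", spec.name)
            return Prediction(spec.name, None, "", "skipped", "runner unavailable")
        return _validate(spec, raw, raw, None, len(sequence))

    if shutil.which(spec.executable) is None:
        log.warning(
            "executable %r for engine %s not found on PATH; skipping",
            spec.executable, spec.name,
        )
        return Prediction(
            spec.name, None, "", "skipped",
            f"executable {spec.executable!r} not found",
        )

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmpdir = Path(tmp)
        seq_path = tmpdir / "input.fasta"
        seq_path.write_text(f">{sequence.identifier}\n{sequence.residues}\n")
        ct_path = tmpdir / "output.ct"
        argv, stdin_kind = _build_command(spec, seq_path, ct_path, shape)
        stdin_text = (
            sequence.residues + "\n" if stdin_kind == "stdin-seq"
            else sequence.residues + "\n" if spec.output_kind == "vienna"
            else None
        )
        try:
            proc = subprocess.run(
                argv, input=stdin_text, capture_output=True, text=True,
                cwd=tmpdir, timeout=600,
            )
        except (OSError, subprocess.TimeoutExpired) as exc:
            return Prediction(spec.name, None, "", "failed", f"invocation failed: {exc}")
        if proc.returncode != 0:
            return Prediction(
                spec.name, None, proc.stdout + proc.stderr, "failed",
                f"exit code {proc.returncode}",
            )
        return _validate(spec, proc.stdout, proc.stdout, ct_path, len(sequence))


def _validate(
    spec: EngineSpec, raw: str, stdout: str, ct_path: Optional[Path], length: int
) -> Prediction:
    try:
        if spec.runner is not None:
            structure = parse_dotbracket(raw.strip().splitlines()[-1].split()[0],
                                         length=length)
        else:
            structure = _extract_structure(spec, stdout, ct_path, length)
    except (DotBracketError, ValueError, OSError, IndexError) as exc:
        return Prediction(spec.name, None, raw, "failed", f"unparseable output: {exc}")
    structure = SecondaryStructure(
        length=structure.length, pairs=structure.pairs, label=spec.name
    )
    return Prediction(spec.name, structure, raw, "ok", "")
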