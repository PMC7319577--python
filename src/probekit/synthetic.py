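"""Synthetic probing data with known ground truth, and a mock engine.

Chemical probes modify flexible, mostly unpaired nucleotides, so a probed RNA
with a known secondary structure should show high reactivity at unpaired
positions and low reactivity at paired ones.  The generator emulates exactly
that statistical signature: each position draws from a truncated normal whose
mean depends on its pairedness in a ground-truth structure, scaled by an
arbitrary instrument gain, with a configurable fraction of dropped-out
(missing) positions.  It does not emulate capillary-electrophoresis traces,
signal decay along the read, or sequence-dependent reactivity biases.

The default condition — unpaired mean 5x the paired mean, noise standard
deviation half the paired mean — gives a clearly bimodal but noisy profile,
comparable to a decent low-throughput experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engines import EngineSpec
from .probing_io import RNASequence, ReactivityProfile
from .structures import SecondaryStructure, parse_dotbracket

#: Watson-Crick partner used when generating sequences for paired positions.
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# versioned ground-truth topologies used across the test-suite
HAIRPIN_30 = "((((((((((..........))))))))))"
PSEUDOKNOT_40 = "((((....[[[[....))))....]]]]............"
#: three-helix junction, loosely modelled on small riboswitch aptamers
THREE_HELIX_60 = "((((..((((....))))..((((....))))..))))......((((......)))).."


def hairpin_structure() -> SecondaryStructure:
    return parse_dotbracket(HAIRPIN_30, label="hairpin30")


def pseudoknot_structure() -> SecondaryStructure:
    return parse_dotbracket(PSEUDOKNOT_40, label="pseudoknot40")


def three_helix_structure() -> SecondaryStructure:
    return parse_dotbracket(THREE_HELIX_60, label="three_helix60")


@dataclass(frozen=True)
class SynthParams:
    """Generation conditions for one synthetic profile."""

    structure: SecondaryStructure
    paired_mean: float = 1.0
    unpaired_mean: float = 5.0
    noise_sd: float = 0.5
    missing_rate: float = 0.05
    scale: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.structure.length < 1:
            raise ValueError("structure must cover at least one position")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.scale <= 0 or self.paired_mean <= 0 or self.unpaired_mean <= 0:
            raise ValueError("means and scale must be positive")


def synth_sequence(structure: SecondaryStructure, rng: np.random.Generator) -> RNASequence:
    """Random sequence compatible with a structure (WC pairs at paired positions)."""
    letters = list(rng.choice(list("ACGU"), size=structure.length))
    for i, j in structure.pairs:
        letters[j - 1] = _COMPLEMENT[letters[i - 1]]
    return RNASequence(identifier=structure.label or "synthetic", residues="".join(letters))


def synth_profile(params: SynthParams, sequence: Optional[RNASequence] = None) -> ReactivityProfile:
    """Raw (non-normalized) profile drawn from the pairedness-dependent model.

    Value at position ``i``: ``scale * max(0, N(mean_i, noise_sd))`` with
    ``mean_i`` the paired or unpaired mean according to the ground-truth
    structure; the position is missing with probability ``missing_rate``.
    Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.structure.length
    if sequence is None:
        sequence = synth_sequence(params.structure, rng)
    elif len(sequence) != n:
        raise ValueError("sequence length must match structure length")
    paired = np.zeros(n, dtype=bool)
    for i, j in params.structure.pairs:
        paired[[i - 1, j - 1]] = True
    means = np.where(paired, params.paired_mean, params.unpaired_mean)
    values = params.scale * np.maximum(0.0, rng.normal(means, params.noise_sd))
    measured = rng.random(n) >= params.missing_rate
    values = np.where(measured, values, np.nan)
    return ReactivityProfile(
        sequence=sequence, values=values, measured=measured,
        probe="SHAPE", normalized=False,
        origin=f"synthetic(seed={params.seed})",
    )


def paired_mask(structure: SecondaryStructure) -> np.ndarray:
    """Boolean mask of positions involved in any base pair."""
    mask = np.zeros(structure.length, dtype=bool)
    for i, j in structure.pairs:
        mask[[i - 1, j - 1]] = True
    return mask


def synth_qushape(profile: ReactivityProfile, reactivity_column: str = "areaDiff") -> str:
    """Render a raw profile as QuShape-style TSV (seqNum, seqRNA, reactivity).

    Missing positions get blank reactivity cells; parsing the result with
    :func:`probekit.probing_io.parse_qushape` reproduces the profile.
    """
    if len(profile) == 0:
        raise ValueError("profile is empty")
    lines = [f"seqNum\tseqRNA\t{reactivity_column}"]
    for i in range(len(profile)):
        cell = f"{profile.values[i]:.6f}" if profile.measured[i] else ""
        lines.append(f"{i + 1}\t{profile.sequence[i]}\t{cell}")
    return "\n".join(lines) + "\n"


def make_mock_engine(
    script: dict[str, str],
    name: str = "mock",
    modes: frozenset = frozenset({"PREDICT"}),
    accepts_reactivities: bool = False,
) -> EngineSpec:
    """In-process engine whose output is scripted per sequence.

    ``script`` maps residue strings to the dot-bracket text the engine should
    emit.  A sequence absent from the script behaves like an uninstalled
    executable (the prediction is skipped); scripted text that fails to parse
    at the right length yields a failed prediction, exercising the same
    validation path as a real subprocess engine.
    """
    def runner(sequence: RNASequence, reactivities) -> Optional[str]:
        return script.get(sequence.residues)

    return EngineSpec(
        name=name,
        modes=modes,
        accepts_reactivities=accepts_reactivities,
        executable=f"<mock:{name}>",
        output_kind="dotbracket-line",
        runner=runner,
    )


def mock_registry(structures: list[str], sequence: RNASequence) -> list[EngineSpec]:
    """One mock engine per scripted structure, all answering for ``sequence``."""
    return [
        make_mock_engine({sequence.residues: db}, name=f"mock{i + 1}")
        for i, db in enumerate(structures)
    ]
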