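"""Shared fixtures: random structures, brute-force oracles, a synthetic PDB."""

from __future__ import annotations

import numpy as np
import pytest

from probekit.probing_io import ReactivityProfile, RNASequence
from probekit.structures import SecondaryStructure


def brute_force_factor(values) -> float:
    """Independent normalization-divisor oracle: full sort, slice, mean.

    Selects ceil(10%) of the values, drops the highest ceil(20%-of-selected),
    and averages the rest — written without sharing code with the library.
    """
    import math

    vals = sorted(values, reverse=True)
    n_sel = math.ceil(0.10 * len(vals))
    n_exc = math.ceil(0.20 * n_sel)
    window = vals[n_exc:n_sel]
    assert window, "oracle called below the minimum usable N"
    return float(np.mean(window))


def random_structure(
    rng: np.random.Generator, length: int, n_pairs: int | None = None
) -> SecondaryStructure:
    """Random base-pair set (crossing allowed), each position used once."""
    positions = list(rng.permutation(length) + 1)
    if n_pairs is None:
        n_pairs = int(rng.integers(0, length // 2 + 1))
    pairs = set()
    for _ in range(n_pairs):
        if len(positions) < 2:
            break
        i, j = positions.pop(), positions.pop()
        pairs.add((min(i, j), max(i, j)))
    return SecondaryStructure(length=length, pairs=frozenset(pairs))


def make_profile(
    values, sequence: str | None = None, normalized: bool = False, probe: str = "SHAPE"
) -> ReactivityProfile:
    """Profile from a plain value list; None entries become missing."""
    vals = np.array([np.nan if v is None else float(v) for v in values])
    measured = ~np.isnan(vals)
    seq = sequence or ("ACGU" * (len(vals) // 4 + 1))[: len(vals)]
    return ReactivityProfile(
        sequence=RNASequence("test", seq),
        values=vals,
        measured=measured,
        probe=probe,
        normalized=normalized,
    )


def make_pdb(sequence: str, chain: str = "A", start_resseq: int = 1,
             atoms_per_residue: int = 3, bfactor: float = 50.0) -> str:
    """Minimal synthetic RNA PDB text with standard fixed columns."""
    lines = ["HEADER    SYNTHETIC RNA FOR TESTING"]
    serial = 1
    names = ["P", "C4'", "N1"]
    for k, letter in enumerate(sequence):
        resseq = start_resseq + k
        for a in range(atoms_per_residue):
            name = names[a % len(names)]
            x, y, z = 1.0 * serial, 2.0 * k, 0.5 * a
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} {letter:>3s} {chain}{resseq:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{bfactor:6.2f}"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hairpin_profile():
    """Noiseless hairpin profile: paired=1, unpaired=5, scale 1."""
    from probekit.synthetic import SynthParams, hairpin_structure, synth_profile

    params = SynthParams(
        structure=hairpin_structure(), paired_mean=1.0, unpaired_mean=5.0,
        noise_sd=0.0, missing_rate=0.0, scale=1.0, seed=1,
    )
    return synth_profile(params)
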