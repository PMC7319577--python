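"""Map reactivities onto the B-factor field of a PDB structure.

The temperature-factor (B-factor) columns of ATOM/HETATM records — fixed
columns 61-66 in the PDB standard, written ``%6.2f`` — are repurposed to
carry normalized reactivity, so any viewer that colors by B-factor shows the
probing signal on the 3D model.  The rewrite is purely textual: every byte
outside the temperature-factor columns of the records it touches is
preserved, which keeps otherwise-nonstandard files intact.

Residues without a readout, and residues that could not be matched to the
profile, receive the display sentinel ``-1.00``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ChainNotFoundError, FormatError, ReconciliationError
from .probing_io import ReactivityProfile

log = logging.getLogger(__name__)

#: PDB residue names that denote RNA nucleotides, by one-letter code
_RESNAME_TO_LETTER = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "RA": "A", "RC": "C", "RG": "G", "RU": "U",
    "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U", "URI": "U",
    # DNA names tolerated; T is read as U, as in sequence input
    "DA": "A", "DC": "C", "DG": "G", "DT": "U", "T": "U",
}


@dataclass
class ResidueMapping:
    """Correspondence between profile positions and chain residues."""

    chain: str
    #: (profile position, residue key) for letter-consistent matches, where a
    #: residue key is the (resSeq, insertion-code) pair from the ATOM records
    matched: list = field(default_factory=list)
    #: residue keys that fall outside the profile after the offset
    unmatched: list = field(default_factory=list)
    #: (profile position, residue key, residue letter, profile letter)
    mismatches: list = field(default_factory=list)


def _is_atom(line: str) -> bool:
    return line.startswith(("ATOM  ", "HETATM", "ATOM\t"))


def _chain_residues(pdb_text: str, chain: str):
    """Residue keys and letters of one chain, in file (author) order, model 1."""
    residues: list[tuple[tuple[str, str], str]] = []
    seen: set[tuple[str, str]] = set()
    chains: set[str] = set()
    in_model = 0
    for line in pdb_text.splitlines():
        if line.startswith("MODEL"):
            in_model += 1
            if in_model > 1:
                log.info("multiple MODEL records; using model 1 only")
                break
        if line.startswith("ENDMDL"):
            break
        if not _is_atom(line) or len(line) < 27:
            continue
        chains.add(line[21])
        if line[21] != chain:
            continue
        key = (line[22:26].strip(), line[26].strip())
        if key in seen:
            continue
        seen.add(key)
        resname = line[17:20].strip().upper()
        residues.append((key, _RESNAME_TO_LETTER.get(resname, "?")))
    if not residues:
        raise ChainNotFoundError(
            f"chain {chain!r} not found; file contains chains "
            f"{sorted(c for c in chains if c.strip()) or '(none)'}"
        )
    return residues


def match_residues(
    pdb_text: str, profile: ReactivityProfile, chain: str, offset: int = 0
) -> ResidueMapping:
    """Match the k-th residue of a chain to profile position ``k + offset``.

    Residues are taken in author order within model 1.  Matches whose residue
    letter disagrees with the profile letter are reported, not silently
    mapped; more than 10% letter disagreement raises
    :class:`ReconciliationError` listing the positions.
    """
    residues = _chain_residues(pdb_text, chain)
    mapping = ResidueMapping(chain=chain)
    n = len(profile)
    for k, (key, letter) in enumerate(residues, start=1):
        pos = k + offset
        if not 1 <= pos <= n:
            mapping.unmatched.append(key)
            continue
        if letter == profile.sequence[pos - 1]:
            mapping.matched.append((pos, key))
        else:
            mapping.mismatches.append((pos, key, letter, profile.sequence[pos - 1]))
    attempted = len(mapping.matched) + len(mapping.mismatches)
    if attempted and len(mapping.mismatches) / attempted > 0.10:
        listing = ", ".join(
            f"pos {p} ({a}!={b})" for p, _, a, b in mapping.mismatches[:15]
        )
        raise ReconciliationError(
            f"{len(mapping.mismatches)}/{attempted} residue letters disagree with "
            f"the profile (offset {offset} likely wrong): {listing}"
        )
    return mapping


def inject_bfactors(
    pdb_text: str, mapping: ResidueMapping, profile: ReactivityProfile
) -> str:
    """Write reactivities into the temperature-factor columns of the chain.

    Matched residues receive their position's value; missing-readout and
    unmatched residues receive ``-1.00``.  Bytes outside columns 61-66 of the
    rewritten ATOM/HETATM records are untouched; records of other chains are
    returned verbatim.
    """
    value_by_key: dict[tuple[str, str], float] = {}
    for pos, key in mapping.matched:
        value_by_key[key] = (
            float(profile.values[pos - 1]) if profile.measured[pos - 1] else -1.0
        )
    for key in mapping.unmatched:
        value_by_key[key] = -1.0
    for pos, key, _, _ in mapping.mismatches:
        value_by_key[key] = -1.0

    out_lines = []
    in_model = 0
    past_first_model = False
    for lineno, line in enumerate(pdb_text.splitlines(keepends=True), start=1):
        body = line.rstrip("\r\n")
        eol = line[len(body):]
        if body.startswith("MODEL"):
            in_model += 1
            past_first_model = in_model > 1
        if (
            not past_first_model
            and _is_atom(body)
            and len(body) >= 27
            and body[21] == mapping.chain
        ):
            key = (body[22:26].strip(), body[26].strip())
            if key in value_by_key:
                if len(body) < 66:
                    raise FormatError(
                        f"ATOM record too short for temperature-factor columns",
                        line=lineno,
                    )
                body = body[:60] + f"{value_by_key[key]:6.2f}" + body[66:]
        out_lines.append(body + eol)
    return "".join(out_lines)
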