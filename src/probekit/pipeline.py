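"""End-to-end orchestration of the four analysis modes.

A run turns one configuration into a :class:`ResultBundle` plus a directory
of artifacts:

* probing modes (``shape``/``dms``/``cmct``): parse QuShape or pre-normalized
  reactivity input, reconcile against the reference sequence, trim the region
  of interest, normalize each replicate with the 2-8% rule, average, write the
  reactivity file, run the mode's prediction engines, and render heatmap,
  barplot and VARNA exports (plus PDB B-factor injection when a 3D structure
  is supplied);
* ``predict`` mode: run the eight sequence-only engines, compute the >=50%
  base-pair consensus over the successful predictions, and export structures
  and tables — no reactivity artifacts exist in this mode.

Identical configuration and inputs (with deterministic engines) produce
byte-identical text and table outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import pdb_map, probing_io, visualize
from .engines import build_registry, run_engine
from .errors import ConfigurationError, LengthError
from .normalize import SUSCEPTIBILITY, average_profiles, normalize_profile
from .probing_io import (
    ReactivityProfile,
    RegionOfInterest,
    RNASequence,
    canonicalize_sequence,
    parse_qushape,
    read_reactivity_file,
    reconcile,
    write_reactivity_file,
)
from .structures import ConsensusStructure, SecondaryStructure, consensus, parse_dotbracket, write_dotbracket

log = logging.getLogger(__name__)

PROBING_MODES = ("shape", "dms", "cmct")
DEFAULT_MAX_LEN = 600


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    ``qushape_texts`` / ``reactivity_text`` carry file *contents* (the CLI
    reads the files); exactly one kind may be present in probing modes and
    neither in predict mode.
    """

    mode: str
    sequence: str  # bare text or FASTA
    job_name: str = "probekit-run"
    qushape_texts: list = field(default_factory=list)
    qushape_origins: list = field(default_factory=list)
    qushape_column: str = probing_io.DEFAULT_QUSHAPE_COLUMN
    reactivity_text: Optional[str] = None
    trim5: int = 0
    trim3: int = 0
    nucleotide_specific: bool = False
    mask_unsusceptible: bool = False  # write -999 at non-susceptible positions
    user_structure: Optional[str] = None  # dot-bracket text
    pdb_text: Optional[str] = None
    pdb_chain: str = "A"
    pdb_offset: int = 0
    engine_paths: dict = field(default_factory=dict)
    engines_override: Optional[list] = None  # list[EngineSpec], e.g. mocks
    outdir: str = "probekit_results"
    max_len: int = DEFAULT_MAX_LEN
    strict: bool = False
    scheme: Optional[str] = None
    grey_out: bool = False
    layouts: tuple = ("radiate", "circular", "linear")
    varna_jar: Optional[str] = None

    def validate(self) -> None:
        if self.mode not in PROBING_MODES + ("predict",):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        has_probing_input = bool(self.qushape_texts) or self.reactivity_text is not None
        if self.mode in PROBING_MODES and not has_probing_input:
            raise ConfigurationError(
                f"{self.mode} mode needs QuShape or reactivity input"
            )
        if self.mode == "predict" and has_probing_input:
            raise ConfigurationError("predict mode takes no probing input")
        if self.qushape_texts and self.reactivity_text is not None:
            raise ConfigurationError(
                "provide either QuShape files or a reactivity file, not both"
            )


@dataclass
class ResultBundle:
    """All artifacts of one run."""

    mode: str
    sequence: RNASequence
    profile: Optional[ReactivityProfile] = None
    normalization: list = field(default_factory=list)  # NormalizationResult per replicate
    predictions: list = field(default_factory=list)  # Prediction
    consensus: Optional[ConsensusStructure] = None
    user_structure: Optional[SecondaryStructure] = None
    table: Optional[pd.DataFrame] = None
    manifest: list = field(default_factory=list)  # Path
    run_log: dict = field(default_factory=dict)

    def ok_predictions(self) -> list:
        return [p for p in self.predictions if p.status == "ok"]


def _probe_of(mode: str) -> str:
    return mode.upper() if mode in PROBING_MODES else "SHAPE"


def _prepare_profile(config: RunConfig, reference: RNASequence, outdir: Path, bundle: ResultBundle) -> ReactivityProfile:
    """Parse, reconcile, trim and normalize the probing input."""
    probe = _probe_of(config.mode)
    roi = RegionOfInterest(config.trim5, config.trim3)
    target_seq = RNASequence(
        reference.identifier,
        reference.residues[config.trim5 : len(reference) - config.trim3]
        if (config.trim5 or config.trim3) else reference.residues,
    )

    if config.reactivity_text is not None:
        # pre-normalized values over the reference; trim alongside the sequence
        full = read_reactivity_file(
            config.reactivity_text, reference, probe=probe, origin="reactivities"
        )
        return probing_io.apply_roi(full, roi)

    replicates = []
    origins = list(config.qushape_origins) or [
        f"qushape{i + 1}" for i in range(len(config.qushape_texts))
    ]
    for text, origin in zip(config.qushape_texts, origins):
        prof = parse_qushape(
            text, reactivity_column=config.qushape_column, probe=probe, origin=origin
        )
        report = reconcile(prof, reference, strict=config.strict)
        if not report.empty:
            log.warning("%s: sequence differs from reference: %s", origin, report.describe())
            bundle.run_log.setdefault("reconciliation", {})[origin] = report.describe()
        prof = probing_io.apply_roi(prof, roi)
        # replicates must agree with each other after trimming
        if replicates:
            reconcile(prof, replicates[0].sequence, strict=True)
        result = normalize_profile(prof, nucleotide_specific=config.nucleotide_specific)
        bundle.normalization.append(result)
        bundle.run_log.setdefault("normalization", []).append(
            {
                "origin": origin,
                "factor": result.factor,
                "n_selected": result.n_selected,
                "n_excluded": result.n_excluded,
                "subset": result.subset,
            }
        )
        replicates.append(result.profile)
    if len(replicates) == 1:
        profile = replicates[0]
    else:
        profile = average_profiles(replicates)
    # the analysis sequence is the trimmed reference
    if profile.sequence.residues != target_seq.residues and not config.strict:
        log.warning("using QuShape-derived sequence for downstream analysis")
    return profile


def _engine_input_profile(config: RunConfig, profile: ReactivityProfile) -> ReactivityProfile:
    """Profile whose serialization feeds the engines.

    With ``mask_unsusceptible`` set, positions a DMS/CMCT probe cannot modify
    are written as missing (-999) so the engines ignore them.
    """
    if not config.mask_unsusceptible:
        return profile
    letters = SUSCEPTIBILITY[profile.probe]
    measured = profile.measured.copy()
    for i, c in enumerate(profile.sequence.residues):
        if c not in letters:
            measured[i] = False
    return ReactivityProfile(
        sequence=profile.sequence, values=profile.values, measured=measured,
        probe=profile.probe, normalized=True, origin=profile.origin,
    )


def run(config: RunConfig) -> ResultBundle:
    """Execute one full analysis run and write all artifacts to ``outdir``."""
    config.validate()
    reference = canonicalize_sequence(config.sequence, identifier=config.job_name)
    if len(reference) > config.max_len:
        raise LengthError(
            f"sequence is {len(reference)} nt; it cannot exceed {config.max_len} "
            "nucleotides (prediction accuracy degrades with length)"
        )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(mode=config.mode, sequence=reference)
    bundle.run_log["mode"] = config.mode
    bundle.run_log["job"] = config.job_name

    reactivity_path: Optional[Path] = None
    if config.mode in PROBING_MODES:
        profile = _prepare_profile(config, reference, outdir, bundle)
        bundle.profile = profile
        bundle.sequence = profile.sequence
        reactivity_path = outdir / "reactivities.txt"
        reactivity_path.write_text(write_reactivity_file(profile))
        bundle.manifest.append(reactivity_path)
        engine_input = _engine_input_profile(config, profile)
        engine_path = reactivity_path
        if config.mask_unsusceptible:
            engine_path = outdir / "reactivities_engine_input.txt"
            engine_path.write_text(write_reactivity_file(engine_input))
            bundle.manifest.append(engine_path)
    else:
        profile = None
        engine_path = None

    # --- predictions -----------------------------------------------------
    registry = (
        list(config.engines_override)
        if config.engines_override is not None
        else build_registry(config.mode.upper(), config.engine_paths or None)
    )
    seq_for_engines = bundle.sequence
    for spec in registry:
        pred = run_engine(spec, seq_for_engines, reactivities=engine_path)
        bundle.predictions.append(pred)
        bundle.run_log.setdefault("engines", []).append(
            {"engine": pred.engine, "status": pred.status, "message": pred.message}
        )
    ok = bundle.ok_predictions()
    if config.mode in PROBING_MODES and not ok:
        log.warning("all probing-mode engines skipped or failed; "
                    "structure-dependent artifacts will be absent")

    if config.user_structure:
        bundle.user_structure = parse_dotbracket(
            config.user_structure, length=len(bundle.sequence), label="user"
        )

    if config.mode == "predict" and len(ok) >= 2:
        bundle.consensus = consensus([p.structure for p in ok])
    elif config.mode == "predict" and ok:
        log.warning("only %d successful prediction(s); consensus needs two", len(ok))

    # --- visual artifacts -------------------------------------------------
    if profile is not None:
        scheme = visualize.default_scheme(profile.probe, config.scheme)
        bundle.manifest += visualize.heatmap(profile, outdir / "heatmap", scheme=scheme)
        bundle.manifest += visualize.barplot(profile, outdir / "barplot")

    structures_to_draw = [(p.engine, p.structure) for p in ok]
    if bundle.user_structure is not None:
        structures_to_draw.append(("user", bundle.user_structure))
    if bundle.consensus is not None:
        structures_to_draw.append(("consensus", bundle.consensus.structure))
    for name, structure in structures_to_draw:
        for layout in config.layouts:
            written = visualize.varna_export(
                bundle.sequence, structure,
                outdir / f"varna_{_safe(name)}_{layout}",
                profile=profile, layout=layout,
                grey_out=config.grey_out, varna_jar=config.varna_jar,
            )
            bundle.manifest += [
                v for v in written.values() if isinstance(v, Path)
            ]

    if config.pdb_text is not None and profile is not None:
        mapping = pdb_map.match_residues(
            config.pdb_text, profile, config.pdb_chain, config.pdb_offset
        )
        out_pdb = outdir / "reactivities_bfactor.pdb"
        out_pdb.write_text(pdb_map.inject_bfactors(config.pdb_text, mapping, profile))
        bundle.manifest.append(out_pdb)
        bundle.run_log["pdb"] = {
            "chain": mapping.chain,
            "matched": len(mapping.matched),
            "unmatched": len(mapping.unmatched),
            "mismatches": len(mapping.mismatches),
        }

    # --- tables and text files -------------------------------------------
    bundle.table = build_results_table(bundle, job_name=config.job_name)
    bundle.manifest += write_results_table(
        bundle, outdir / "results.xlsx", outdir / "results.csv"
    )
    preds_path = outdir / "all_predictions.txt"
    write_all_predictions(bundle, preds_path)
    bundle.manifest.append(preds_path)
    if config.mode == "predict" and bundle.consensus is not None:
        # ready-to-submit sequence + consensus structure for 3D modelling
        submit = outdir / "sequence_with_consensus.txt"
        submit.write_text(
            f">{config.job_name}\n{bundle.sequence.residues}\n"
            f"{write_dotbracket(bundle.consensus.structure)}\n"
        )
        bundle.manifest.append(submit)

    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(bundle.run_log, indent=2, default=str) + "\n")
    bundle.manifest.append(log_path)
    return bundle


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in name)


def build_results_table(bundle: ResultBundle, job_name: str = "") -> pd.DataFrame:
    """Results table: one row per record, five parts plus per-nucleotide cells.

    Parts: Name (job), Method (record kind / engine), Filename (input origin
    + mode), Full string (sequence, reactivity series or dot-bracket), then
    one cell per nucleotide.  Missing reactivities display as -1.
    """
    n = len(bundle.sequence)
    cols = [f"N{i + 1}" for i in range(n)]
    rows = []

    def add_row(method: str, filename: str, full: str, cells: list):
        if len(cells) != n:
            raise ValueError(
                f"row {method!r} has {len(cells)} cells for {n} positions"
            )
        rows.append(
            {"Name": job_name, "Method": method, "Filename": filename,
             "Full string": full, **dict(zip(cols, cells))}
        )

    add_row("Sequence", bundle.mode, bundle.sequence.residues,
            list(bundle.sequence.residues))
    if bundle.profile is not None:
        # fixed-format strings keep CSV and XLSX byte-for-byte identical
        cells = [
            f"{v:.3f}" if m else "-1"
            for v, m in zip(bundle.profile.values, bundle.profile.measured)
        ]
        add_row(
            "Reactivity",
            f"{bundle.profile.origin or 'probing'} ({bundle.mode})",
            ";".join(cells),
            cells,
        )
    for pred in bundle.ok_predictions():
        db = write_dotbracket(pred.structure)
        add_row(pred.engine, bundle.mode, db, list(db))
    if bundle.user_structure is not None:
        db = write_dotbracket(bundle.user_structure)
        add_row("User structure", bundle.mode, db, list(db))
    if bundle.consensus is not None:
        db = write_dotbracket(bundle.consensus.structure)
        add_row("Consensus", bundle.mode, db, list(db))
    return pd.DataFrame(rows)


def write_results_table(bundle: ResultBundle, xlsx_path, csv_path) -> list:
    """Write the results table as XLSX and CSV with identical content."""
    df = bundle.table if bundle.table is not None else build_results_table(bundle)
    xlsx_path, csv_path = Path(xlsx_path), Path(csv_path)
    df.to_excel(xlsx_path, index=False)
    df.to_csv(csv_path, index=False)
    return [xlsx_path, csv_path]


def write_all_predictions(bundle: ResultBundle, path) -> Path:
    """Write the sequence plus one labeled dot-bracket line per prediction.

    Skipped and failed engines are listed in a trailing comment block.  With
    zero successful predictions the file still contains the sequence and a
    notice (and a warning is logged).
    """
    path = Path(path)
    lines = [bundle.sequence.residues]
    ok = bundle.ok_predictions()
    for pred in ok:
        lines.append(f"{write_dotbracket(pred.structure)}  # {pred.engine}")
    if bundle.user_structure is not None:
        lines.append(f"{write_dotbracket(bundle.user_structure)}  # user")
    if bundle.consensus is not None:
        lines.append(f"{write_dotbracket(bundle.consensus.structure)}  # consensus")
    if not ok:
        log.warning("no successful predictions to write")
        lines.append("# no successful predictions")
    leftover = [p for p in bundle.predictions if p.status != "ok"]
    for pred in leftover:
        lines.append(f"# {pred.status}: {pred.engine} ({pred.message})")
    path.write_text("\n".join(lines) + "\n")
    return path
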