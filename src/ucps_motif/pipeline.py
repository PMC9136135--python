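"""Orchestration: run the full analysis from a config and write reports.

Stage order: read cohorts -> differential k-mer motifs -> class-level
tests (triacidic, KKX, their disjunction, and each with S/T/Y context)
-> per-protein feature table -> structural proximity for proteins with a
mapped PDB chain. Every stage is deterministic given the config and
inputs, so identical runs produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    class_enrichment,
    class_sty_enrichment,
    differential_motifs,
    rows_to_dataframe,
)
from .proximity import FEATURE_COLUMNS, feature_table
from .sequence_io import ProteinRecord, read_fasta
from .structure_proximity import (
    CoverageError,
    MappingError,
    load_chain,
    map_spans,
    structural_proximity_flag,
)

logger = logging.getLogger("ucps_motif")

STRUCTURE_COLUMNS = [
    "protein_id", "pdb_path", "chain", "class_a", "class_b",
    "min_distance_A", "within_thresholds", "mapped_fraction", "status",
]


@dataclass
class AnalysisConfig:
    """All knobs of one analysis run.

    Defaults encode the analysis constants: the 30% differential
    prevalence constraint (``min_ratio`` 1.3), sequence-proximity
    thresholds of 3 and 5 residues, an S/T/Y window of 3 residues, and
    structural thresholds of 10 and 15 Å.
    """

    positive_fasta: str = ""
    negative_fasta: str = ""
    k_list: List[int] = field(default_factory=lambda: [3])
    mirror: bool = False
    min_ratio: float = 1.3
    top_n: int = 10
    lir_mode: str = "core"
    gap_thresholds: List[int] = field(default_factory=lambda: [3, 5])
    sty_window: int = 3
    structure_map: Optional[str] = None  # TSV: protein_id, pdb_path, chain
    distance_thresholds: List[float] = field(default_factory=lambda: [10.0, 15.0])
    atom_mode: str = "all_heavy"
    outdir: str = "ucps_motif_out"
    seed: int = 0
    log_level: str = "INFO"
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if any(k not in (2, 3, 4) for k in self.k_list):
            raise ValueError("k values must be in {2, 3, 4}")
        if self.min_ratio <= 0 or self.top_n <= 0 or self.sty_window <= 0:
            raise ValueError("thresholds must be positive")
        if any(t <= 0 for t in self.gap_thresholds) or any(
            t <= 0 for t in self.distance_thresholds
        ):
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ReportBundle:
    """All tables of one run plus run metadata."""

    enrichment: Dict[int, pd.DataFrame]   # k -> table
    class_tests: pd.DataFrame
    features: pd.DataFrame
    structural: pd.DataFrame
    metadata: Dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _structural_table(
    pos: List[ProteinRecord],
    neg: List[ProteinRecord],
    config: AnalysisConfig,
) -> pd.DataFrame:
    rows: List[Dict] = []
    if not config.structure_map:
        return pd.DataFrame(columns=STRUCTURE_COLUMNS)
    mapping = pd.read_csv(config.structure_map, sep="\t")
    by_id = {r.id: r for r in list(pos) + list(neg)}
    lir_class = "lir" if config.lir_mode == "core" else "lir_extended"
    for _, mrow in mapping.iterrows():
        pid = str(mrow["protein_id"])
        rec = by_id.get(pid)
        if rec is None:
            logger.warning("structure map names unknown protein %r, skipped", pid)
            continue
        try:
            chain = load_chain(mrow["pdb_path"], str(mrow["chain"]), config.atom_mode)
            report = map_spans(rec.sequence, chain)
        except (MappingError, LookupError, ValueError) as exc:
            rows.append(
                dict.fromkeys(STRUCTURE_COLUMNS)
                | {
                    "protein_id": pid,
                    "pdb_path": mrow["pdb_path"],
                    "chain": mrow["chain"],
                    "status": f"error: {exc}",
                }
            )
            continue
        for class_b in ("triacidic", "KKX"):
            try:
                _, dist, _pair = structural_proximity_flag(
                    chain, rec.sequence, lir_class, class_b,
                    threshold=max(config.distance_thresholds),
                    atom_mode=config.atom_mode,
                )
                within = ";".join(
                    f"{t:g}:{dist <= t}" for t in config.distance_thresholds
                )
                rows.append(
                    {
                        "protein_id": pid,
                        "pdb_path": mrow["pdb_path"],
                        "chain": mrow["chain"],
                        "class_a": lir_class,
                        "class_b": class_b,
                        "min_distance_A": round(dist, 3),
                        "within_thresholds": within,
                        "mapped_fraction": round(report.mapped_fraction, 3),
                        "status": "ok",
                    }
                )
            except CoverageError as exc:
                rows.append(
                    {
                        "protein_id": pid,
                        "pdb_path": mrow["pdb_path"],
                        "chain": mrow["chain"],
                        "class_a": lir_class,
                        "class_b": class_b,
                        "min_distance_A": None,
                        "within_thresholds": None,
                        "mapped_fraction": round(report.mapped_fraction, 3),
                        "status": f"no measurable pair: {exc}",
                    }
                )
    return pd.DataFrame(rows, columns=STRUCTURE_COLUMNS)


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the full pipeline; raises with the stage name on failure."""
    stage = "read_cohorts"
    try:
        pos = read_fasta(config.positive_fasta, cohort="positive")
        neg = read_fasta(config.negative_fasta, cohort="negative")
        if not pos or not neg:
            raise ValueError("cohort FASTA contained no records")

        stage = "differential_motifs"
        from .motif_engine import enumerate_motifs

        enrichment_tables: Dict[int, pd.DataFrame] = {}
        for k in config.k_list:
            rows = differential_motifs(
                pos, neg, k,
                min_ratio=config.min_ratio,
                top_n=config.top_n,
                mirror=config.mirror,
            )
            m = len(enumerate_motifs(k, config.mirror)) if config.bonferroni else None
            enrichment_tables[k] = rows_to_dataframe(rows, bonferroni_m=m)

        stage = "class_enrichment"
        class_rows = [
            class_enrichment(pos, neg, "triacidic", class_name="triacidic"),
            class_enrichment(pos, neg, "KKX", class_name="KKX"),
            class_enrichment(
                pos, neg, ["triacidic", "KKX"], class_name="triacidic|KKX"
            ),
            class_sty_enrichment(
                pos, neg, "triacidic", window=config.sty_window,
                class_name="triacidic+STY",
            ),
            class_sty_enrichment(
                pos, neg, "KKX", window=config.sty_window, class_name="KKX+STY"
            ),
        ]
        class_df = rows_to_dataframe(class_rows)

        stage = "features"
        feats = pd.concat(
            [
                feature_table(
                    cohort_records,
                    lir_mode=config.lir_mode,
                    gap_threshold=min(config.gap_thresholds),
                    sty_window=config.sty_window,
                )
                for cohort_records in (pos, neg)
            ],
            ignore_index=True,
        )[FEATURE_COLUMNS]

        stage = "structural_proximity"
        structural = _structural_table(pos, neg, config)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    metadata = {
        "config": asdict(config),
        "version": __version__,
        "n_pos": len(pos),
        "n_neg": len(neg),
        "input_checksums": {
            "positive_fasta": _sha256(Path(config.positive_fasta)),
            "negative_fasta": _sha256(Path(config.negative_fasta)),
        },
    }
    return ReportBundle(
        enrichment=enrichment_tables,
        class_tests=class_df,
        features=feats,
        structural=structural,
        metadata=metadata,
    )


def write_reports(bundle: ReportBundle, outdir: str | Path) -> pd.DataFrame:
    """Write all tables as TSV plus a JSON summary, log and manifest.

    Returns the manifest DataFrame (file name, sha256). Table output is
    deterministic; the timestamp appears only in the log file.
    """
    import datetime

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    for k, df in bundle.enrichment.items():
        p = outdir / f"differential_motifs_k{k}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    for name, df in (
        ("class_tests", bundle.class_tests),
        ("features", bundle.features),
        ("structural_proximity", bundle.structural),
    ):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)

    feats = bundle.features
    summary = {
        "metadata": bundle.metadata,
        "class_tests": bundle.class_tests.to_dict(orient="records"),
        "feature_counts": {
            "n_proteins": int(len(feats)),
            "has_triacidic": int(feats["has_triacidic"].sum()),
            "has_kkx": int(feats["has_kkx"].sum()),
            "has_lir": int(feats["has_lir"].sum()),
            "lacking_lir": int((~feats["has_lir"]).sum()),
        },
        "top_motifs": {
            str(k): df["motif"].tolist() for k, df in bundle.enrichment.items()
        },
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(summary_path)

    log_path = outdir / "run.log"
    log_path.write_text(
        f"{datetime.datetime.now().isoformat()} ucps_motif {__version__} "
        f"wrote {len(written)} files to {outdir}\n"
    )

    manifest = pd.DataFrame(
        [{"file": p.name, "sha256": _sha256(p)} for p in written],
        columns=["file", "sha256"],
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
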