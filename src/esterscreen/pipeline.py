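"""End-to-end driver: counts + annotations -> DE table + candidate shortlist.

Runs the two-library Poisson test, screens the up-regulated genes
against the esterase/lipase whitelist, and writes the DE table, the
candidate table, an annotation-coverage summary and a JSON run log
with configuration and input/output hashes, so a run is reproducible
from (inputs, config).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dge import TestConfig, test_library
from .io import read_annotations, read_counts, read_whitelist, write_table
from .screen import CandidateScreen, TermWhitelist, annotation_coverage

logger = logging.getLogger("esterscreen")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    counts_path: str | Path = ""
    annotations_path: str | Path = ""
    out_dir: str | Path = "esterscreen_out"
    n1: int | None = None  # None: use count-column sums
    n2: int | None = None
    test: TestConfig = field(default_factory=TestConfig)
    whitelist_path: str | Path | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run test -> screen -> write outputs; returns a summary dict.

    Output files (under ``config.out_dir``): de_results.tsv,
    candidates.tsv, coverage.tsv, run_log.json.  Any stage error
    propagates before anything is written.
    """
    counts_path = Path(config.counts_path)
    ann_path = Path(config.annotations_path)

    counts, sums = read_counts(counts_path)
    annotations = read_annotations(ann_path)
    whitelist: TermWhitelist | None = (
        read_whitelist(config.whitelist_path) if config.whitelist_path else None
    )
    n1 = config.n1 if config.n1 is not None else (sums[0] if sums else None)
    n2 = config.n2 if config.n2 is not None else (sums[1] if sums else None)
    if not n1 or not n2:
        raise ValueError("library sizes unavailable: pass n1/n2 or non-empty counts")

    logger.info("testing %d genes (N1=%d, N2=%d)", len(counts), n1, n2)
    results = test_library(counts, n1, n2, config.test)

    screener = CandidateScreen(whitelist=whitelist).fit(results, annotations)
    candidates = screener.candidates_
    logger.info(
        "%d DE genes, %d up, %d candidates (%d up genes unannotated)",
        int(results["is_de"].sum()),
        int((results["is_de"] & (results["direction"] == "up")).sum()),
        len(candidates),
        screener.n_unannotated_,
    )

    annotated = int((annotations["go_terms"].ne("") & annotations["go_terms"].ne("NA")
                     | annotations["kegg_ko"].ne("NA")).sum())
    coverage = annotation_coverage(
        {"any": annotated, "KEGG": int(annotations["kegg_ko"].ne("NA").sum())},
        total=len(counts),
    )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_table(results, out_dir / "de_results.tsv")
    cand_out = candidates.rename(columns={"matched_terms": "terms"})
    write_table(cand_out, out_dir / "candidates.tsv")
    write_table(coverage, out_dir / "coverage.tsv")

    run_log = {
        "version": __version__,
        "inputs": {
            str(counts_path): _sha256(counts_path),
            str(ann_path): _sha256(ann_path),
        },
        "library_sizes": {"n1": int(n1), "n2": int(n2)},
        "test_config": {
            "fold_threshold": config.test.fold_threshold,
            "alpha": config.test.alpha,
            "pseudocount": config.test.pseudocount,
            "use_fdr": config.test.use_fdr,
        },
        "outputs": {
            name: _sha256(out_dir / name)
            for name in ("de_results.tsv", "candidates.tsv", "coverage.tsv")
        },
        "n_genes": len(counts),
        "n_de": int(results["is_de"].sum()),
        "n_candidates": len(candidates),
        "n_up_unannotated": screener.n_unannotated_,
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")
    return run_log
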