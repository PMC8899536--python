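"""Annotation-whitelist screening of up-regulated genes.

Takes the per-gene differential-transcription table and a gene
annotation table (KEGG K-number plus GO accessions), keeps the genes
that are significantly up-regulated AND carry at least one
esterase/lipase/hydrolase term from a whitelist, and reports annotation
coverage per database.  Matching is exact accession equality with no
GO-graph propagation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "TermWhitelist",
    "CandidateScreen",
    "default_whitelist",
    "screen",
    "annotation_coverage",
]

_GO_RE = re.compile(r"^GO:\d{7}$")
_KO_RE = re.compile(r"^K\d{5}$")

# Esterase/lipase annotation terms of the screened candidate genes:
# KEGG orthology K-numbers and GO accessions covering lipase,
# carboxylesterase, pectinesterase and related hydrolase/lyase activity.
DEFAULT_KEGG = frozenset(
    {
        "K16815", "K14788", "K01051", "K01050", "K02332", "K13333",
        "K01956", "K03927", "K14675", "K09252", "K17648", "K12389",
        "K01049",
    }
)
DEFAULT_GO = frozenset(
    {
        "GO:0016042",  # lipid catabolic process
        "GO:0016787",  # hydrolase activity
        "GO:0016829",  # lyase activity
        "GO:0080030",  # methyl indole-3-acetate esterase activity
        "GO:0009395",  # phospholipid catabolic process
        "GO:0004806",  # triglyceride lipase activity
        "GO:0004372",  # glycine hydroxymethyltransferase activity
    }
)

CANDIDATE_COLUMNS = ["gene_id", "fold_change", "matched_terms", "annotation_label"]


@dataclass(frozen=True)
class TermWhitelist:
    """Set of KEGG K-numbers and GO accessions defining candidate function."""

    kegg_set: frozenset[str] = field(default_factory=frozenset)
    go_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.kegg_set and not self.go_set:
            raise ValueError("whitelist needs at least one KEGG or GO term")
        bad_ko = [k for k in self.kegg_set if not _KO_RE.match(k)]
        bad_go = [g for g in self.go_set if not _GO_RE.match(g)]
        if bad_ko or bad_go:
            raise ValueError(f"malformed whitelist terms: {bad_ko + bad_go}")

    def __contains__(self, term: str) -> bool:
        return term in self.kegg_set or term in self.go_set


def default_whitelist() -> TermWhitelist:
    """Whitelist of esterification-enzyme annotation terms (13 K-numbers, 7 GO)."""
    return TermWhitelist(kegg_set=DEFAULT_KEGG, go_set=DEFAULT_GO)


def _parse_go_terms(raw) -> frozenset[str]:
    """Split a semicolon-separated GO field; 'NA'/empty means no terms."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return frozenset()
    raw = str(raw).strip()
    if raw in ("", "NA"):
        return frozenset()
    terms = frozenset(t.strip() for t in raw.split(";") if t.strip())
    bad = [t for t in terms if not _GO_RE.match(t)]
    if bad:
        raise ValueError(f"malformed GO accessions: {bad}")
    return terms


class CandidateScreen(BaseEstimator):
    """Filter differential-transcription results to esterification candidates.

    Parameters
    ----------
    whitelist : TermWhitelist or None
        Terms that mark an annotation as esterification-relevant; the
        built-in esterase/lipase whitelist when None.

    Attributes
    ----------
    candidates_ : pandas.DataFrame
        gene_id, fold_change, matched_terms (frozenset), annotation_label,
        sorted by descending fold change (ties by gene_id).
    n_unannotated_ : int
        Up-regulated DE genes that had no annotation record at all.
    """

    def __init__(self, whitelist: TermWhitelist | None = None):
        self.whitelist = whitelist

    def fit(self, results: pd.DataFrame, annotations: pd.DataFrame) -> "CandidateScreen":
        """Screen ``results`` (from the DE test) against ``annotations``.

        ``annotations`` has columns gene_id, kegg_ko, go_terms
        (semicolon-separated accessions; 'NA' allowed in either field)
        and optionally annotation_label.
        """
        wl = self.whitelist if self.whitelist is not None else default_whitelist()
        for frame, name in ((results, "results"), (annotations, "annotations")):
            if frame["gene_id"].duplicated().any():
                raise ValueError(f"duplicate gene_id in {name} table")

        ann = annotations.set_index("gene_id")
        up = results[(results["is_de"]) & (results["direction"] == "up")]

        rows = []
        n_unannotated = 0
        for rec in up.itertuples(index=False):
            if rec.gene_id not in ann.index:
                n_unannotated += 1
                continue
            arow = ann.loc[rec.gene_id]
            ko = str(arow["kegg_ko"]).strip() if pd.notna(arow["kegg_ko"]) else "NA"
            terms = set(_parse_go_terms(arow["go_terms"]))
            if ko != "NA":
                if not _KO_RE.match(ko):
                    raise ValueError(f"malformed K-number {ko!r} for {rec.gene_id}")
                terms.add(ko)
            matched = frozenset(t for t in terms if t in wl)
            if not matched:
                continue
            label = arow.get("annotation_label", "") if hasattr(arow, "get") else ""
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "fold_change": rec.fold_change,
                    "matched_terms": matched,
                    "annotation_label": "" if pd.isna(label) else str(label),
                }
            )

        out = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
        out = out.sort_values(
            ["fold_change", "gene_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        self.candidates_ = out
        self.n_unannotated_ = n_unannotated
        return self

    def fit_transform(self, results: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
        return self.fit(results, annotations).candidates_


def screen(
    results: pd.DataFrame,
    annotations: pd.DataFrame,
    whitelist: TermWhitelist | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`CandidateScreen`."""
    return CandidateScreen(whitelist=whitelist).fit_transform(results, annotations)


def _round_half_up(value: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def annotation_coverage(annotated_counts: dict[str, int], total: int) -> pd.DataFrame:
    """Percent of genes annotated per database, rounded half-up to 2 decimals.

    Returns a DataFrame with columns database, annotated, total, pct.
    """
    if total < 1:
        raise ValueError("total must be positive")
    rows = []
    for database, annotated in annotated_counts.items():
        if annotated < 0 or annotated > total:
            raise ValueError(
                f"annotated count {annotated} for {database} outside [0, {total}]"
            )
        pct = _round_half_up(100.0 * annotated / total)
        rows.append(
            {"database": database, "annotated": annotated, "total": total, "pct": pct}
        )
    return pd.DataFrame(rows, columns=["database", "annotated", "total", "pct"])
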