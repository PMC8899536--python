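"""Synthetic two-library count data and assay tables with known truth.

The count generator emulates the statistical structure of a pooled
two-condition RNA-seq design: one library per condition with stated
total sizes N1 and N2, per-gene Poisson counts around gamma-distributed
baseline expression, a minority of genes with planted fold changes, and
a minority of genes carrying esterase/lipase whitelist annotations
(planted candidates plus decoy null genes).  Every draw is reproducible
from a single seed, which feeds three named substreams (rates, counts,
annotations) so partial regeneration is stable.

An optional overdispersion knob mixes gamma noise into the per-library
means (negative-binomial marginals) to probe the Poisson test's
behaviour when its own sampling assumption is violated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen import DEFAULT_GO, DEFAULT_KEGG

__all__ = [
    "SimConfig",
    "simulate_counts",
    "simulate_assay",
    "estimate_error_rates",
]

# GO terms outside the esterase/lipase whitelist, used as background
# annotation for non-candidate genes.
_BACKGROUND_GO = (
    "GO:0008150",  # biological_process
    "GO:0003674",  # molecular_function
    "GO:0005575",  # cellular_component
    "GO:0006412",  # translation
    "GO:0055085",  # transmembrane transport
)


@dataclass
class SimConfig:
    """Study-condition parameters for the count simulator.

    Defaults mirror the pooled two-library design being emulated:
    24,319 genes (the assembled unigene count), single deep library per
    condition, a small DE fraction, and 23 planted whitelist-annotated
    candidates among the up-regulated genes.
    """

    n_genes: int = 24319
    n1: int = 1_000_000
    n2: int = 1_000_000
    baseline_mean: float = 40.0
    baseline_dispersion: float = 0.5  # gamma shape of expression across genes
    de_fraction: float = 0.05
    fold_min: float = 2.0
    fold_max: float = 10.0
    whitelist_fraction: float = 0.01
    planted_candidates: int = 23
    planted_min_expected: float = 50.0  # floor on a planted gene's expected count
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n1 < 1 or self.n2 < 1:
            raise ValueError("n_genes, n1, n2 must be positive")
        if self.baseline_mean <= 0 or self.baseline_dispersion <= 0:
            raise ValueError("baseline_mean and baseline_dispersion must be positive")
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must be in [0, 1)")
        if not (self.fold_min > 1 and self.fold_min <= self.fold_max):
            raise ValueError("need 1 < fold_min <= fold_max")
        if not 0 <= self.whitelist_fraction <= 1:
            raise ValueError("whitelist_fraction must be in [0, 1]")
        n_de = int(round(self.de_fraction * self.n_genes))
        if self.planted_candidates < 0 or self.planted_candidates > n_de:
            raise ValueError(
                f"planted_candidates={self.planted_candidates} exceeds the "
                f"{n_de} DE genes implied by de_fraction"
            )
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")


def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[int, int], pd.DataFrame]:
    """Draw a two-library count table with planted truth.

    Returns ``(counts, annotations, (n1, n2), truth)``:

    counts
        gene_id, count_group1, count_group2.
    annotations
        gene_id, kegg_ko, go_terms (semicolon-separated), annotation_label.
    truth
        gene_id, true_fold, is_planted_de, has_whitelist_term,
        expected_x, expected_y.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_rates, rng_counts, rng_ann = (np.random.default_rng(s) for s in ss.spawn(3))
    n = config.n_genes

    shape = config.baseline_dispersion
    base = rng_rates.gamma(shape, config.baseline_mean / shape, size=n)
    base = np.maximum(base, 1e-3 * config.baseline_mean)  # avoid empty genes

    n_de = int(round(config.de_fraction * n))
    de_idx = rng_rates.choice(n, size=n_de, replace=False)
    folds = np.ones(n)
    folds[de_idx] = rng_rates.uniform(config.fold_min, config.fold_max, size=n_de)
    planted_idx = np.sort(de_idx[:config.planted_candidates])

    # Planted candidates must be comfortably expressed: floor their
    # baseline so the group-2 expectation clears planted_min_expected.
    if len(planted_idx):
        floor = config.planted_min_expected * base.sum() / config.n2
        base[planted_idx] = np.maximum(base[planted_idx], floor)

    rate1 = base * folds
    mu_x = rate1 * (config.n1 / rate1.sum())
    mu_y = base * (config.n2 / base.sum())

    if config.overdispersion > 0:
        od = config.overdispersion
        mu_x = mu_x * rng_counts.gamma(1.0 / od, od, size=n)
        mu_y = mu_y * rng_counts.gamma(1.0 / od, od, size=n)
    x = rng_counts.poisson(mu_x)
    y = rng_counts.poisson(mu_y)

    gene_ids = np.array([f"Unigene{i:05d}" for i in range(n)])
    counts = pd.DataFrame(
        {"gene_id": gene_ids, "count_group1": x, "count_group2": y}
    )

    # annotations: planted candidates get whitelist terms; decoy
    # whitelist terms go to a fraction of null genes; the rest carry
    # background GO terms only.
    kegg_pool = sorted(DEFAULT_KEGG)
    go_pool = sorted(DEFAULT_GO)
    is_planted = np.zeros(n, dtype=bool)
    is_planted[planted_idx] = True
    null_idx = np.setdiff1d(np.arange(n), de_idx)
    n_decoys = int(round(config.whitelist_fraction * len(null_idx)))
    decoy_idx = rng_ann.choice(null_idx, size=n_decoys, replace=False)
    has_wl = is_planted.copy()
    has_wl[decoy_idx] = True

    kegg_col = np.full(n, "NA", dtype=object)
    go_col = np.empty(n, dtype=object)
    label_col = np.full(n, "", dtype=object)
    background = rng_ann.choice(_BACKGROUND_GO, size=n)
    for i in range(n):
        if has_wl[i]:
            kegg_col[i] = rng_ann.choice(kegg_pool)
            go_col[i] = rng_ann.choice(go_pool)
            label_col[i] = "Esterase/lipase"
        else:
            go_col[i] = background[i]
    annotations = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "kegg_ko": kegg_col,
            "go_terms": go_col,
            "annotation_label": label_col,
        }
    )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_fold": folds,
            "is_planted_de": np.isin(np.arange(n), de_idx),
            "has_whitelist_term": has_wl,
            "expected_x": mu_x if config.overdispersion == 0 else rate1 * config.n1 / rate1.sum(),
            "expected_y": mu_y if config.overdispersion == 0 else base * config.n2 / base.sum(),
        }
    )
    return counts, annotations, (config.n1, config.n2), truth


def simulate_assay(
    seed: int,
    true_conversions: dict[str, float],
    initial_acid_mM: float = 10.0,
    noise_sd: float = 0.0,
    curve_concs: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 10.0),
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Emit a standard-curve table and an assay table with known truth.

    Each ester gets its own calibration line (slope and intercept drawn
    once per ester), a triplicate dilution series, and one assay
    response at the detector reading implied by its true conversion.
    Gaussian noise of ``noise_sd`` response units is added to every
    measured response.

    Returns ``(curve_table, assay_table, truth)`` where truth maps
    ester name to the generating conversion percentage.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for ester, conv in true_conversions.items():
        if not 0 <= conv <= 100:
            raise ValueError(f"true conversion for {ester} outside [0, 100]")
    rng = np.random.default_rng(seed)

    curve_rows, assay_rows = [], []
    for ester in sorted(true_conversions):
        slope = rng.uniform(80.0, 120.0)
        intercept = rng.uniform(0.0, 10.0)
        for conc in curve_concs:
            for _ in range(n_replicates):
                resp = slope * conc + intercept + rng.normal(0.0, noise_sd)
                curve_rows.append(
                    {"analyte": ester, "conc_mM": conc, "response": resp}
                )
        true_conc = true_conversions[ester] / 100.0 * initial_acid_mM
        resp = slope * true_conc + intercept + rng.normal(0.0, noise_sd)
        assay_rows.append(
            {
                "sample_id": "optimized",
                "substrate_acid": ester.replace("ethyl ", "") + " acid",
                "ester": ester,
                "initial_acid_mM": initial_acid_mM,
                "response": resp,
            }
        )
    return (
        pd.DataFrame(curve_rows),
        pd.DataFrame(assay_rows),
        dict(true_conversions),
    )


def estimate_error_rates(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    candidates: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Compare calls against planted truth.

    type_I
        Fraction of true-null genes called differentially transcribed.
    power
        Fraction of planted DE genes called differentially transcribed.
    sensitivity / precision (when ``candidates`` is given)
        Candidate recovery against the planted whitelist-annotated DE
        genes.
    """
    if set(results["gene_id"]) != set(truth["gene_id"]):
        raise ValueError("results and truth cover different gene sets")
    merged = results.merge(truth, on="gene_id", validate="one_to_one")
    nulls = merged[~merged["is_planted_de"]]
    planted = merged[merged["is_planted_de"]]
    out = {
        "type_I": float(nulls["is_de"].mean()) if len(nulls) else float("nan"),
        "power": float(planted["is_de"].mean()) if len(planted) else float("nan"),
    }
    if candidates is not None:
        target = set(
            truth.loc[
                truth["is_planted_de"] & truth["has_whitelist_term"], "gene_id"
            ]
        )
        called = set(candidates["gene_id"])
        tp = len(called & target)
        out["sensitivity"] = tp / len(target) if target else float("nan")
        out["precision"] = tp / len(called) if called else float("nan")
    return out
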