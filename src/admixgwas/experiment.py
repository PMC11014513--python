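"""Desk-scale replicated GWAS simulation designs.

Two designs are orchestrated. The array-style design computes PCs from the
cohort itself under several pre-processing regimes, simulates traits for
causal variants chosen by loading / frequency-difference strata, fits each
covariate strategy (no adjustment, admixture proportion, one PC, several
PCs) and aggregates chromosome-level spurious-association counts over
replicates. The sequence-style design swaps the cohort PCs for a constructed
pair of "PCs" — the admixture proportion plus an artificial component that
loads on the causal variant and a partner variant on a different chromosome —
and contrasts adjusting for [pi] against [pi, z] at the stricter sequencing
significance threshold.

Genotypes are held fixed within a replicate block and trait noise is redrawn
per replicate; blocks re-simulate the cohort so PC sampling variability is
represented as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .gwas import (
    CHI2_1_MEDIAN,
    GENOME_WIDE_ARRAY,
    GENOME_WIDE_SEQUENCE,
    ArtificialPcSpec,
    CovariateSpec,
    build_covariates,
    count_spurious,
    genomic_control_lambda,
    scan,
)
from .pca import compute_diagnostics, run_pca, standardize_genotypes
from .preprocess import PruneParams, apply_regime
from .sim import (
    AncestralFrequencyPanel,
    LdFeatureSpec,
    SimConfig,
    simulate_cohort,
    simulate_panel,
    true_global_ancestry,
)

__all__ = [
    "ScenarioConfig",
    "ExperimentReport",
    "select_causal_variants",
    "run_array_style",
    "run_sequence_style",
    "manhattan_table",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Settings for a replicated simulation scenario.

    ``n_blocks`` cohorts are simulated; each contributes
    ``traits_per_block`` trait replicates per (causal variant, beta,
    strategy) cell. ``features`` are injected into every cohort.
    """

    panel: AncestralFrequencyPanel | None = None
    n: int = 1000
    admixture_mean: float = 0.8
    admixture_sd: float = 0.1
    features: tuple = ()
    regimes: tuple = ("none", "both")
    beta_grid: tuple = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    beta_pi: float = 0.0
    causal_variants: tuple | None = None
    n_per_stratum: int = 2
    n_blocks: int = 5
    traits_per_block: int = 40
    threshold: float = GENOME_WIDE_ARRAY
    k_pcs: int = 4
    prune_params: PruneParams = field(default_factory=PruneParams)
    artificial: ArtificialPcSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1 or self.traits_per_block < 1:
            raise ValueError("replicate counts must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class ExperimentReport:
    """Replicated-design output: per-replicate rows and aggregated summary."""

    design: str
    summary: pd.DataFrame
    per_replicate: pd.DataFrame
    pc_flags: pd.DataFrame
    config: ScenarioConfig

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(outdir / f"{self.design}_summary.tsv", sep="\t", index=False)
        self.per_replicate.to_csv(
            outdir / f"{self.design}_replicates.tsv", sep="\t", index=False
        )
        self.pc_flags.to_csv(outdir / f"{self.design}_pc_flags.tsv", sep="\t", index=False)
        return outdir


def select_causal_variants(
    diag,
    panel: AncestralFrequencyPanel,
    top_per_chrom: int = 10,
    low_loading_cutoff: float = 0.02,
    large_diff: float = 0.6,
    small_diff: float = 0.005,
) -> pd.DataFrame:
    """Stratify candidate causal variants by PC loading and frequency difference.

    Strata (a variant may fall in several): ``high_loading`` — the
    ``top_per_chrom`` variants per chromosome per PC by |corr| with that PC;
    ``highest_on_chrom`` — the single top variant per chromosome per PC;
    ``low_loading`` — |corr| below ``low_loading_cutoff`` on every PC;
    ``large_freq_diff`` / ``small_freq_diff`` — |p1 - p0| above / below the
    corresponding cutoff. The loading measure is the PC-genotype correlation
    from a regime-``none`` PCA. Empty strata are omitted.
    """
    abs_corr = diag.pc_variant_abs_corr
    chrom = np.asarray(diag.chrom, dtype=str)
    rows = []
    for pc in range(abs_corr.shape[0]):
        for c in pd.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            vals = abs_corr[pc, idx]
            finite = idx[np.isfinite(vals)]
            if finite.size == 0:
                continue
            order = finite[np.argsort(abs_corr[pc, finite])[::-1]]
            for j in order[:top_per_chrom]:
                rows.append({"variant": int(j), "stratum": "high_loading", "pc": pc + 1})
            rows.append(
                {"variant": int(order[0]), "stratum": "highest_on_chrom", "pc": pc + 1}
            )
    with np.errstate(invalid="ignore"):
        low = np.all(abs_corr < low_loading_cutoff, axis=0)
    for j in np.flatnonzero(low):
        rows.append({"variant": int(j), "stratum": "low_loading", "pc": 0})
    absd = np.abs(panel.freq_diff)
    for j in np.flatnonzero(absd > large_diff):
        rows.append({"variant": int(j), "stratum": "large_freq_diff", "pc": 0})
    for j in np.flatnonzero(absd < small_diff):
        rows.append({"variant": int(j), "stratum": "small_freq_diff", "pc": 0})
    return pd.DataFrame(rows, columns=["variant", "stratum", "pc"])


def equal_size_features(
    panel: AncestralFrequencyPanel,
    chroms=("2", "4", "6", "9"),
    variants_per_feature: int = 20,
    max_span_bp: int = 400_000,
    coupling: float = 0.9,
    latent_freq0: float = 0.2,
    latent_freq1: float = 0.8,
    start_offset: int = 10,
) -> tuple:
    """Build equal-strength single-region LD features, one per chromosome.

    Each feature's region is chosen to contain exactly
    ``variants_per_feature`` consecutive panel variants spanning at most
    ``max_span_bp`` (inside the default pruning window). Equal variant counts
    give the features near-degenerate PCA eigenvalues, so sample PCs mix
    them — the situation in which an adjusted PC correlates with several
    regions at once. The latent factors are ancestry-differentiated by
    default (frequencies 0.2 / 0.8), as structural features in admixed
    cohorts typically are, so a feature-region causal variant also carries
    ancestry confounding.
    """
    features = []
    for c in chroms:
        idx = np.flatnonzero(np.asarray(panel.chrom, dtype=str) == str(c))
        if len(idx) < start_offset + variants_per_feature:
            raise ValueError(f"chromosome {c} has too few variants")
        for s in range(start_offset, len(idx) - variants_per_feature + 1):
            window = idx[s : s + variants_per_feature]
            span = panel.pos_bp[window[-1]] - panel.pos_bp[window[0]]
            gap_after = (
                panel.pos_bp[idx[s + variants_per_feature]]
                - panel.pos_bp[window[-1]]
                if s + variants_per_feature < len(idx)
                else max_span_bp
            )
            gap_before = panel.pos_bp[window[0]] - panel.pos_bp[idx[s - 1]]
            if span <= max_span_bp and gap_after > 1 and gap_before > 1:
                features.append(
                    LdFeatureSpec(
                        regions=(
                            (
                                str(c),
                                int(panel.pos_bp[window[0]]),
                                int(panel.pos_bp[window[-1]]),
                            ),
                        ),
                        coupling=coupling,
                        latent_freq0=latent_freq0,
                        latent_freq1=latent_freq1,
                    )
                )
                break
        else:
            raise ValueError(f"no {variants_per_feature}-variant window on {c}")
    return tuple(features)


def _block_seed(config: ScenarioConfig, block: int) -> int:
    return int(substream(config.seed, "block", str(block)).integers(2**31))


def _simulate_block(config: ScenarioConfig, block: int):
    panel = config.panel if config.panel is not None else simulate_panel(seed=config.seed)
    cohort = simulate_cohort(
        panel,
        SimConfig(
            n=config.n,
            admixture_mean=config.admixture_mean,
            admixture_sd=config.admixture_sd,
            features=tuple(config.features),
            seed=_block_seed(config, block),
        ),
    )
    return panel, cohort


def _spurious_counts(pvalues: np.ndarray, chrom, causal_chrom, threshold: float):
    """Per-replicate chromosome-level spurious counts from an (m, r) p matrix."""
    chrom = np.asarray(chrom, dtype=str)
    off = chrom != str(causal_chrom)
    sig = pvalues[off] < threshold
    chroms_off = chrom[off]
    counts = np.zeros(pvalues.shape[1], dtype=int)
    for c in pd.unique(chroms_off):
        counts += sig[chroms_off == c].any(axis=0)
    return counts


def run_array_style(config: ScenarioConfig) -> ExperimentReport:
    """Array-style design: cohort PCs under each regime, stratified causal variants."""
    rep_rows = []
    flag_rows = []
    for block in range(config.n_blocks):
        panel, cohort = _simulate_block(config, block)
        g = cohort.genotypes.astype(float)
        pi_hat = true_global_ancestry(cohort.ancestry)
        pcas, kept_by_regime = {}, {}
        needed = set(config.regimes) | {"none"}
        for regime in needed:
            rr = apply_regime(
                g, panel.chrom, panel.pos_bp, regime, prune_params=config.prune_params
            )
            kept_by_regime[regime] = rr.kept
            X = standardize_genotypes(g[:, rr.kept])
            pcas[regime] = run_pca(X, k=config.k_pcs, regime=regime)
        diag_none = compute_diagnostics(
            pcas["none"],
            g[:, kept_by_regime["none"]],
            cohort.pi,
            panel.chrom[kept_by_regime["none"]],
        )
        for regime in config.regimes:
            kept = kept_by_regime[regime]
            d = compute_diagnostics(
                pcas[regime], g[:, kept], cohort.pi, panel.chrom[kept]
            )
            for pc in range(config.k_pcs):
                flag_rows.append(
                    {
                        "block": block,
                        "regime": regime,
                        "pc": pc + 1,
                        "flagged": bool(d.local_feature_flags[pc]),
                        "ancestry_corr": float(d.pc_ancestry_corr[pc]),
                    }
                )

        if config.causal_variants is not None:
            causal_table = pd.DataFrame(
                {"variant": list(config.causal_variants), "stratum": "explicit", "pc": 0}
            )
        else:
            causal_table = select_causal_variants(diag_none, panel)
            picks = []
            sel_rng = substream(config.seed, "causal_select", str(block))
            for stratum, sub in causal_table.groupby("stratum"):
                variants = sub["variant"].unique()
                take = min(config.n_per_stratum, len(variants))
                chosen = sel_rng.choice(variants, size=take, replace=False)
                picks.append(
                    pd.DataFrame({"variant": chosen, "stratum": stratum, "pc": 0})
                )
            causal_table = pd.concat(picks, ignore_index=True)

        strategies = {"none": np.empty((config.n, 0)), "ancestry": pi_hat[:, None]}
        for regime in config.regimes:
            pca_res = pcas[regime]
            strategies[f"pc1_{regime}"] = pca_res.scores[:, :1]
            strategies[f"pcs{config.k_pcs}_{regime}"] = pca_res.scores[:, : config.k_pcs]

        for row in causal_table.itertuples():
            causal = int(row.variant)
            causal_chrom = panel.chrom[causal]
            for beta in config.beta_grid:
                rng = substream(
                    config.seed, "traits", str(block), str(causal), f"{beta:g}"
                )
                Y = (
                    beta * g[:, causal][:, None]
                    + config.beta_pi * cohort.pi[:, None]
                    + rng.standard_normal((config.n, config.traits_per_block))
                )
                for name, w in strategies.items():
                    res = scan(Y, g, w)
                    counts = _spurious_counts(
                        res["pvalue"], panel.chrom, causal_chrom, config.threshold
                    )
                    lambdas = np.nanmedian(res["wald"] ** 2, axis=0) / CHI2_1_MEDIAN
                    for r in range(config.traits_per_block):
                        rep_rows.append(
                            {
                                "block": block,
                                "stratum": row.stratum,
                                "causal": causal,
                                "beta": beta,
                                "strategy": name,
                                "rep": r,
                                "spurious": int(counts[r]),
                                "lambda_gc": float(lambdas[r]),
                            }
                        )

    per_rep = pd.DataFrame(rep_rows)
    summary = _summarize(per_rep)
    return ExperimentReport(
        design="array",
        summary=summary,
        per_replicate=per_rep,
        pc_flags=pd.DataFrame(flag_rows),
        config=config,
    )


def run_sequence_style(config: ScenarioConfig) -> ExperimentReport:
    """Sequence-style design: [pi] versus [pi, z] with an artificial PC."""
    if config.artificial is None:
        raise ValueError("run_sequence_style requires config.artificial")
    art = config.artificial
    threshold = config.threshold if config.threshold != GENOME_WIDE_ARRAY else GENOME_WIDE_SEQUENCE
    rep_rows = []
    for block in range(config.n_blocks):
        panel, cohort = _simulate_block(config, block)
        if panel.chrom[art.variant_a] == panel.chrom[art.variant_b]:
            raise ValueError("artificial PC variants must sit on distinct chromosomes")
        g = cohort.genotypes.astype(float)
        causal = art.variant_a
        causal_chrom = panel.chrom[causal]
        partner_chrom = panel.chrom[art.variant_b]
        z = build_covariates(
            CovariateSpec(kind="artificial", artificial=art),
            pi=cohort.pi,
            genotypes=g,
            chrom=panel.chrom,
            seed=_block_seed(config, block),
        )
        strategies = {"pi": cohort.pi[:, None], "pi_z": z}
        for beta in config.beta_grid:
            rng = substream(config.seed, "traits", str(block), str(causal), f"{beta:g}")
            Y = (
                beta * g[:, causal][:, None]
                + config.beta_pi * cohort.pi[:, None]
                + rng.standard_normal((config.n, config.traits_per_block))
            )
            for name, w in strategies.items():
                res = scan(Y, g, w)
                counts = _spurious_counts(
                    res["pvalue"], panel.chrom, causal_chrom, threshold
                )
                partner_mask = np.asarray(panel.chrom, dtype=str) == partner_chrom
                partner_hit = (res["pvalue"][partner_mask] < threshold).any(axis=0)
                lambdas = np.nanmedian(res["wald"] ** 2, axis=0) / CHI2_1_MEDIAN
                for r in range(config.traits_per_block):
                    rep_rows.append(
                        {
                            "block": block,
                            "stratum": "artificial",
                            "causal": causal,
                            "beta": beta,
                            "strategy": name,
                            "rep": r,
                            "spurious": int(counts[r]),
                            "partner_hit": bool(partner_hit[r]),
                            "lambda_gc": float(lambdas[r]),
                        }
                    )
    per_rep = pd.DataFrame(rep_rows)
    summary = _summarize(per_rep, extra=("partner_hit",))
    return ExperimentReport(
        design="sequence",
        summary=summary,
        per_replicate=per_rep,
        pc_flags=pd.DataFrame(
            columns=["block", "regime", "pc", "flagged", "ancestry_corr"]
        ),
        config=config,
    )


def _summarize(per_rep: pd.DataFrame, extra=()) -> pd.DataFrame:
    """Aggregate per-replicate counts two ways.

    ``mean_spurious`` pools every replicate in the cell; ``variant_mean``
    averages per-causal-variant means (both reductions are reported because
    strata contain unequal variant counts).
    """
    agg = {"spurious": "mean", "lambda_gc": "mean"}
    for col in extra:
        agg[col] = "mean"
    pooled = (
        per_rep.groupby(["stratum", "strategy", "beta"], as_index=False)
        .agg(agg)
        .rename(columns={"spurious": "mean_spurious", "lambda_gc": "mean_lambda"})
    )
    by_variant = (
        per_rep.groupby(["stratum", "strategy", "beta", "causal"], as_index=False)[
            "spurious"
        ]
        .mean()
        .groupby(["stratum", "strategy", "beta"], as_index=False)["spurious"]
        .mean()
        .rename(columns={"spurious": "variant_mean_spurious"})
    )
    return pooled.merge(by_variant, on=["stratum", "strategy", "beta"])


def manhattan_table(
    results: pd.DataFrame, threshold: float = GENOME_WIDE_ARRAY
) -> pd.DataFrame:
    """Ordered per-variant table with -log10 p and a significance flag.

    Sorted by (chromosome, position); the flag uses strict inequality, so a
    p-value exactly at the threshold is not significant.
    """
    if len(results) == 0:
        raise ValueError("empty result table")
    df = results.copy()
    df["chrom"] = df["chrom"].astype(str)
    chrom_key = df["chrom"].map(
        lambda c: (0, int(c)) if c.isdigit() else (1, 0)
    )
    df = (
        df.assign(_key=chrom_key)
        .sort_values(["_key", "chrom", "pos_bp"], kind="stable")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["pvalue"])
    df["significant"] = df["pvalue"] < threshold
    return df
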