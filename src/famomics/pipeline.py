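"""End-to-end orchestration, genomic window overlap and over-representation.

`run_pipeline` wires the stages together on simulated (or user-supplied)
inputs: pedigree -> detection filter -> normalization -> deconvolution ->
residualization -> per-feature variance-components scan -> cross-omic
screen -> bivariate genetic correlations -> window overlap, writing TSV
tables, a structured run log and a summary document.  Runs are
deterministic given the seed; reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import deconvolution, pedigree, preprocess, simulate, varcomp
from .correlation import genetic_correlation, phenotypic_screen

logger = logging.getLogger(__name__)

__all__ = ["window_overlap", "ora", "run_pipeline", "GeneSetCollection"]


# ---------------------------------------------------------------------------
# window overlap (CpG sites vs extended transcript regions)
# ---------------------------------------------------------------------------


def _check_builds(*frames):
    builds = {f.attrs.get("build") for f in frames if f.attrs.get("build")}
    if len(builds) > 1:
        raise ValueError(f"inputs are on different genome builds: {sorted(builds)}")


def window_overlap(transcripts: pd.DataFrame, cpgs: pd.DataFrame, window_bp: int):
    """Count CpG sites falling within transcript regions extended by
    ``window_bp`` on both sides.

    Both inputs use 0-based half-open ``chromosome``/``start``/``end``
    columns (a CpG may be a single-base interval).  Extension is floored
    at zero.  A site counts once per chromosome no matter how many
    extended regions it overlaps; overlap is half-open, so a site at
    position ``end + window_bp`` is just outside.  Returns (per-chromosome
    Series, genome-wide total).
    """
    _check_builds(transcripts, cpgs)
    counts: dict[str, int] = {}
    for chrom in sorted(set(transcripts["chromosome"]) | set(cpgs["chromosome"])):
        tx = transcripts[transcripts["chromosome"] == chrom]
        cg = cpgs[cpgs["chromosome"] == chrom]
        if tx.empty or cg.empty:
            counts[chrom] = 0
            continue
        starts = np.maximum(tx["start"].to_numpy(int) - window_bp, 0)
        ends = tx["end"].to_numpy(int) + window_bp
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        # merge the extended regions so each site is tested once
        merged_s, merged_e = [starts[0]], [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        ms = np.array(merged_s)
        me = np.array(merged_e)
        cs = cg["start"].to_numpy(int)
        ce = cg["end"].to_numpy(int) if "end" in cg else cs + 1
        # merged regions are disjoint and sorted: a site [cs, ce) overlaps
        # one iff the first region ending after cs starts before ce
        i = np.searchsorted(me, cs, side="right")
        inb = i < len(ms)
        hit = np.zeros(len(cs), dtype=bool)
        hit[inb] = ms[i[inb]] < ce[inb]
        counts[chrom] = int(hit.sum())
    series = pd.Series(counts, name=f"cpg_within_{window_bp}bp").sort_index()
    return series, int(series.sum())


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------


class GeneSetCollection(dict):
    """Named gene sets; symbols upper-cased on load."""

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets = cls()
        for line in Path(path).read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = {g.strip().upper() for g in genes if g.strip()}
            if genes:
                sets[name] = genes
        return sets


def ora(hit_genes, universe, gene_sets) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hit_genes`` in each set.

    p is the upper tail P(X >= overlap) for X ~ Hypergeom(universe size,
    set size within universe, number of hits); BH adjustment across sets.
    Hits must be contained in the universe.
    """
    hits = {str(g).upper() for g in hit_genes}
    uni = {str(g).upper() for g in universe}
    stray = sorted(hits - uni)
    if stray:
        raise ValueError(f"hit gene(s) not in the universe: {stray}")
    M, N = len(uni), len(hits)
    rows = []
    for name, genes in gene_sets.items():
        genes = {str(g).upper() for g in genes} & uni
        K = len(genes)
        k = len(genes & hits)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append({"set": name, "set_size": K, "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

_GROUPING_6_TO_3 = {
    "type1": "lymphocytes",
    "type2": "lymphocytes",
    "type3": "lymphocytes",
    "type4": "lymphocytes",
    "type5": "monocytes",
    "type6": "neutrophils",
}

_DEFAULTS = {
    "preset": "study-like",
    "seed": 7,
    "n_families": 16,
    "n_features": 500,
    "planted_fraction": 0.2,
    "planted_vg": 0.5,
    "planted_vc": 0.3,
    "planted_ve": 0.2,
    "alpha": 0.05,
    "detected_fraction": 0.384,
    "window_bp": 2000,
    "n_bivariate_pairs": 10,
    "pedigree_path": None,
    "outdir": "results/pipeline",
}


@dataclass
class PipelineResult:
    outdir: Path
    pedigree: pedigree.Pedigree
    scan: pd.DataFrame
    scan_summary: pd.DataFrame
    pair_table: pd.DataFrame
    screen: object
    bivariate: pd.DataFrame
    overlap: pd.Series


def _stage_log(handle, stage: str, **info):
    handle.write(json.dumps({"stage": stage, **info}, sort_keys=True) + "\n")


def run_pipeline(config=None, **overrides) -> PipelineResult:
    """Run the full simulate -> filter -> normalize -> deconvolve ->
    residualize -> scan -> screen -> bivariate -> overlap chain.

    ``config`` may be a dict or a path to a YAML file; keyword overrides
    win.  A fraction of simulated features carries a planted familial
    signal (``planted_*``); the rest are pure noise.  All outputs are TSV
    under ``outdir`` plus ``run_log.jsonl`` and ``summary.json``.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = {**_DEFAULTS, **(config or {}), **overrides}
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    log_path = outdir / "run_log.jsonl"
    with open(log_path, "w") as log:
        # outdir is machine-local and excluded so reruns stay byte-identical
        _stage_log(
            log, "config",
            **{k: str(v) for k, v in sorted(cfg.items()) if k != "outdir"},
        )

        # -- pedigree -------------------------------------------------------
        if cfg["pedigree_path"] is not None:
            ppath = Path(cfg["pedigree_path"])
            if not ppath.exists():
                raise FileNotFoundError(f"pedigree file not found: {ppath}")
            ped = pedigree.read_pedigree(ppath)
        else:
            ped = simulate.generate_pedigree(
                simulate.study_like_config(n_families=int(cfg["n_families"]), seed=seed)
            )
        ped.write(outdir / "pedigree.ped")
        _stage_log(log, "pedigree", n_subjects=len(ped), n_families=len(ped.family_ids))

        # -- simulate features: planted familial + null, both omics --------
        n_feat = int(cfg["n_features"])
        n_planted = int(round(cfg["planted_fraction"] * n_feat))
        parts = {}
        for omic, prefix, stage_seed in (("expression", "probe", seed), ("methylation", "cg", seed + 1)):
            planted_cfg = simulate.study_like_config(
                n_families=int(cfg["n_families"]),
                n_features=max(n_planted, 1),
                vg=float(cfg["planted_vg"]), vc=float(cfg["planted_vc"]),
                ve=float(cfg["planted_ve"]),
                beta_sex=0.3, beta_age=0.02, beta_batch=0.3,
                seed=stage_seed,
            )
            null_cfg = simulate.study_like_config(
                n_families=int(cfg["n_families"]),
                n_features=max(n_feat - n_planted, 1),
                vg=0.0, vc=0.0, ve=1.0,
                beta_sex=0.3, beta_age=0.02, beta_batch=0.3,
                seed=stage_seed + 1000,
            )
            cov = simulate.simulate_covariates(ped, planted_cfg)
            fm_p, _ = simulate.simulate_features(ped, planted_cfg, cov, prefix=prefix)
            fm_n, _ = simulate.simulate_features(ped, null_cfg, cov, prefix=prefix)
            fm_n.values.columns = [f"{prefix}_null_{i:05d}" for i in range(fm_n.n_features)]
            values = pd.concat([fm_p.values, fm_n.values], axis=1)
            # raw-scale shift so the log/quantile normalization has work to do
            raw = pd.DataFrame(
                2.0 ** (values + 8.0), index=values.index, columns=values.columns
            )
            fm = preprocess.FeatureMatrix(raw)
            fm, detected = simulate.simulate_detection(
                fm, detected_fraction=float(cfg["detected_fraction"]), seed=stage_seed
            )
            parts[omic] = (fm, cov, [c for c in fm_p.values.columns])
            _stage_log(log, f"simulate_{omic}", n_features=values.shape[1],
                       n_planted=n_planted)

        # -- deconvolution on a simulated mixture --------------------------
        mix = simulate.CellMixConfig()
        signature = simulate.make_signature(mix, seed=seed)
        bulk, true_props = simulate.simulate_mixture(signature, mix, ped, seed=seed)
        props = deconvolution.estimate_proportions(bulk, signature)
        grouped = deconvolution.group_proportions(props, _GROUPING_6_TO_3)
        grouped.write(outdir / "cell_proportions.tsv")
        _stage_log(log, "deconvolution",
                   mae=float(np.abs(props.matrix.to_numpy() - true_props.to_numpy()).mean()))

        # -- per-omic preprocess + scan -------------------------------------
        scans = {}
        residuals = {}
        for omic, (fm, cov, planted_ids) in parts.items():
            fm, filt = preprocess.detection_filter(fm)
            fm = preprocess.normalize(fm)
            cov_full = cov.join(grouped.matrix.add_prefix("prop_"))
            resid, _rep = preprocess.residualize(fm, cov_full)
            scan = varcomp.genome_scan(resid, ped)
            scan["planted"] = scan.index.isin(planted_ids)
            scans[omic] = scan
            residuals[omic] = resid
            scan.to_csv(outdir / f"scan_{omic}.tsv", sep="\t")
            _stage_log(log, f"scan_{omic}", kept=filt.kept, total=filt.total,
                       n_significant=int((scan["p"] <= cfg["alpha"]).sum()))

        scan_summary = varcomp.summarize_scan(scans["expression"], alpha=cfg["alpha"])
        scan_summary.to_csv(outdir / "scan_summary.tsv", sep="\t")

        # -- Table-1-style pair correlations --------------------------------
        pairs = pedigree.classify_pairs(ped)
        pair_table = pedigree.pair_correlations(
            residuals["expression"].values, pairs
        )
        pair_table.to_csv(outdir / "pair_correlations.tsv", sep="\t")

        # -- cross-omic screen + bivariate ----------------------------------
        sig_e = scans["expression"].index[scans["expression"]["p"] <= cfg["alpha"]]
        sig_m = scans["methylation"].index[scans["methylation"]["p"] <= cfg["alpha"]]
        screen = None
        bivar_rows = []
        if len(sig_e) and len(sig_m):
            screen = phenotypic_screen(
                residuals["expression"].values[list(sig_e)],
                residuals["methylation"].values[list(sig_m)],
                alpha=float(cfg["alpha"]),
                report_threshold=float(cfg["alpha"]) / 100.0,
            )
            screen.pairs.to_csv(outdir / "phenotypic_pairs.tsv", sep="\t", index=False)
            A = pedigree.compute_additive(ped)
            H = pedigree.compute_household(ped)
            blocks = varcomp.block_structure(A, H)
            top = (
                screen.pairs.nsmallest(int(cfg["n_bivariate_pairs"]), "p")
                if len(screen.pairs)
                else screen.pairs
            )
            for _, row in top.iterrows():
                fit = genetic_correlation(
                    residuals["expression"].values[row["feature_a"]].to_numpy(),
                    residuals["methylation"].values[row["feature_b"]].to_numpy(),
                    A, H, blocks,
                )
                bivar_rows.append(
                    {
                        "feature_a": row["feature_a"], "feature_b": row["feature_b"],
                        "vg1": fit.vg1, "vg2": fit.vg2, "rho_g": fit.rho_g,
                        "rho_c": fit.rho_c, "rho_e": fit.rho_e,
                        "lrt": fit.lrt_rho_g, "p": fit.p_rho_g,
                        "converged": fit.converged,
                    }
                )
            _stage_log(log, "screen", m_total=screen.m_total,
                       n_significant=screen.n_significant)
        bivariate = pd.DataFrame(
            bivar_rows,
            columns=["feature_a", "feature_b", "vg1", "vg2", "rho_g", "rho_c",
                     "rho_e", "lrt", "p", "converged"],
        )
        bivariate.to_csv(outdir / "genetic_correlations.tsv", sep="\t", index=False)

        # -- window overlap --------------------------------------------------
        ann_e = simulate.simulate_annotations(sig_e, seed=seed, feature_length=2000)
        ann_m = simulate.simulate_annotations(sig_m, seed=seed + 1)
        overlap, total = (
            window_overlap(ann_e, ann_m, int(cfg["window_bp"]))
            if len(sig_e) and len(sig_m)
            else (pd.Series(dtype=int), 0)
        )
        overlap.to_frame().to_csv(outdir / "window_overlap.tsv", sep="\t")
        _stage_log(log, "overlap", total=total, window_bp=int(cfg["window_bp"]))

        summary = {
            "n_subjects": len(ped),
            "n_families": len(ped.family_ids),
            "expression_significant": int(len(sig_e)),
            "methylation_significant": int(len(sig_m)),
            "screen_significant": int(screen.n_significant) if screen else 0,
            "overlap_total": total,
            "h2max_mean_all": float(scan_summary.loc["all", "h2_max_mean"]),
            "h2max_mean_significant": float(
                scan_summary.loc["significant", "h2_max_mean"]
            ),
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        _stage_log(log, "done", **summary)

    return PipelineResult(
        outdir=outdir, pedigree=ped, scan=scans["expression"],
        scan_summary=scan_summary, pair_table=pair_table, screen=screen,
        bivariate=bivariate, overlap=overlap,
    )
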