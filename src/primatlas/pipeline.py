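"""End-to-end orchestration: simulate/load -> atlas -> QC -> differential
accessibility -> polarization -> enrichment -> selection -> motifs.

Each stage logs counts in and out of every filter, writes its outputs
as TSV under the run directory, and the final report is a markdown
summary whose numbers are all recomputable from those files. When the
input is a simulation, the planted truth is carried along and the
report additionally contains a confusion matrix and the empirical
false discovery proportion of the state classifier.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from . import diffacc, enrich, motifs, polarize, selection, synthdata
from . import io as pio

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sim: synthdata.SimConfig = field(default_factory=synthdata.SimConfig)
    input_dir: str | None = None  # load a written dataset instead of simulating
    outdir: str = "primatlas_run"
    qc_r: float = 0.85
    fdr: float = 0.05
    fold: float = 2.0
    pwm_threshold: float = 0.8
    match_lo: float = 20.0
    match_hi: float = 80.0
    n_selection_common: int = 100  # matched-common OCRs carried into the zeta test
    n_neutral_regions: int = 30  # common OCR alignments concatenated for the neutral fit
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.match_lo < self.match_hi <= 100):
            raise ValueError("need 0 <= match_lo < match_hi <= 100")
        for name in ("qc_r", "pwm_threshold", "fdr"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fold < 1:
            raise ValueError("fold threshold must be >= 1")


@dataclass
class RunReport:
    state_table: pd.DataFrame
    enrichment: pd.DataFrame
    selection_summary: pd.DataFrame
    motif_summary: dict
    pca_variance: np.ndarray
    confusion: pd.DataFrame | None
    empirical_fdp: float | None
    outdir: Path


def load_dataset(indir) -> synthdata.SimResult:
    """Load a dataset from the plain-text layout of write_dataset."""
    indir = Path(indir)
    cfg = synthdata.SimConfig(**_load_json(indir / "sim_config.json"))
    atlas = pio.read_bed(indir / "atlas.bed")
    atlas.columns = ["chrom", "start", "end", "ocr_id"]
    atlas = atlas.set_index("ocr_id", drop=False)
    counts = pio.read_counts(indir / "counts.tsv")
    meta = pio.read_meta(indir / "meta.tsv")
    peak_sets = {sp: pio.read_bed(indir / f"peaks_{sp}.bed") for sp in atlas_mod.SPECIES}
    omap = pio.read_ortholog_map(indir / "ortholog_map.tsv")
    sequences = pio.read_fasta(indir / "sequences.fa")
    alignments = {
        p.stem: pio.read_fasta(p) for p in sorted((indir / "alignments").glob("*.fa"))
    }
    beds = {
        annot: pio.read_bed(indir / f"{annot}.bed")
        for annot in ("promoter", "enhancer", "eqtl")
        if (indir / f"{annot}.bed").exists()
    }
    tissue = pd.read_csv(indir / "tissue_open.tsv", sep="\t", index_col=0).astype(bool)
    tss = pio.read_bed(indir / "tss.bed")
    de = pd.read_csv(indir / "de_table.tsv", sep="\t")
    truth_path = indir / "truth.tsv"
    truth = None
    if truth_path.exists():
        table = pd.read_csv(truth_path, sep="\t", index_col=0)
        sf = pd.read_csv(indir / "true_size_factors.tsv", sep="\t", index_col=0).iloc[:, 0]
        truth = synthdata.TruthTable(table=table, size_factors=sf)
    tree = selection.PhyloTree((indir / "tree.nwk").read_text(), foreground=cfg.foreground)
    return synthdata.SimResult(
        atlas=atlas, counts=counts, meta=meta, sequences=sequences,
        alignments=alignments, peak_sets=peak_sets, ortholog_map=omap,
        annotations={"beds": beds, "tissue_open": tissue, "tss": tss, "de_table": de},
        truth=truth, tree=tree, pwms=motifs.builtin_pwms(), config=cfg,
    )


def _load_json(path):
    import json

    d = json.loads(Path(path).read_text())
    d["size_factor_range"] = tuple(d["size_factor_range"])
    return d


def run_pipeline(config: RunConfig) -> RunReport:
    out = pio.ensure_dir(config.outdir)
    stage = "simulate"
    try:
        if config.input_dir:
            sim = load_dataset(config.input_dir)
        else:
            sim = synthdata.simulate_dataset(
                dataclasses.replace(config.sim, seed=config.seed)
            )

        # ------------------------------------------------------------ atlas
        stage = "atlas"
        built = atlas_mod.build_union_atlas(sim.peak_sets, sim.ortholog_map)
        # re-key built OCRs to the count matrix's ids via reference coordinates
        key = sim.atlas.reset_index(drop=True)[["ocr_id", "chrom", "start", "end"]]
        merged = built.reset_index(drop=True).merge(
            key, on=["chrom", "start", "end"], how="inner", suffixes=("_built", "")
        )
        atlas = merged.set_index("ocr_id", drop=False)
        logger.info("atlas: %d built, %d matched to count matrix", len(built), len(atlas))
        counts = sim.counts.loc[atlas.index]
        atlas = atlas_mod.filter_zero_count(atlas, counts)
        counts = counts.loc[atlas.index]
        presence = atlas_mod.binary_presence(atlas, sim.peak_sets, sim.ortholog_map)
        tss_assign = atlas_mod.assign_closest_tss(atlas, sim.annotations["tss"])

        # ---------------------------------------------------------- diffacc
        stage = "diffacc"
        retained, corr = diffacc.replicate_qc(counts, sim.meta, r_threshold=config.qc_r)
        counts = counts[retained]
        meta = sim.meta.loc[retained]
        norm = diffacc.size_factors(counts)
        alpha = diffacc.estimate_dispersion(counts, norm, meta)
        fit = diffacc.fit_species_model(counts, norm, alpha, meta)
        species_effect = diffacc.test_species_effect(counts, norm, alpha, meta, fit=fit)
        hc = diffacc.pairwise_contrast(counts, norm, alpha, meta, "human", "chimp", fit=fit)
        hr = diffacc.pairwise_contrast(counts, norm, alpha, meta, "human", "rhesus", fit=fit)
        cr = diffacc.pairwise_contrast(counts, norm, alpha, meta, "chimp", "rhesus", fit=fit)
        pca_coords, pca_var = diffacc.pca_qc(norm, meta)

        # --------------------------------------------------------- polarize
        stage = "polarize"
        calls = polarize.classify_states(
            species_effect, hc, hr, cr, fdr=config.fdr, fc_threshold=config.fold
        )
        any_specific = calls["state"].isin(polarize.SPECIES_SPECIFIC_STATES).any()
        matched = (
            polarize.matched_common_set(
                calls, norm.normalized, atlas, lo=config.match_lo, hi=config.match_hi
            )
            if any_specific
            else []
        )
        calls = polarize.completeness_labels(calls, presence)
        state_table = polarize.state_count_table(calls, matched)

        # ----------------------------------------------------------- enrich
        stage = "enrich"
        groups = {
            s: list(calls.index[calls["state"] == s])
            for s in polarize.SPECIES_SPECIFIC_STATES
            if (calls["state"] == s).any()
        }
        flags = {
            annot: enrich.interval_overlap_flags(atlas, bed)
            for annot, bed in sim.annotations["beds"].items()
        }
        enrichment = (
            enrich.enrichment_table(flags, groups, matched)
            if groups and matched
            else pd.DataFrame()
        )
        tissue = sim.annotations["tissue_open"]
        pleio = {
            g: enrich.pleiotropy_compare(ocrs, matched, tissue)
            for g, ocrs in groups.items()
            if matched
        }
        expr = {
            g: enrich.expression_association(
                ocrs, matched, tss_assign, sim.annotations["de_table"]
            )
            for g, ocrs in groups.items()
            if matched
        }

        # -------------------------------------------------------- selection
        stage = "selection"
        rng = np.random.default_rng(config.seed + 7)
        common_ids = list(calls.index[calls["state"] == "common"])
        neutral_ids = list(
            rng.choice(common_ids, size=min(config.n_neutral_regions, len(common_ids)), replace=False)
        )
        neutral_aln = {
            leaf: "".join(sim.alignments[o][leaf] for o in neutral_ids)
            for leaf in sim.tree.leaves
        }
        fitted_tree = selection.fit_neutral_tree(neutral_aln, sim.tree)
        sel_ids = [
            o
            for s in polarize.SPECIES_SPECIFIC_STATES
            for o in calls.index[calls["state"] == s]
            if o in sim.alignments
        ]
        n_common_sel = min(config.n_selection_common, len(matched))
        sel_ids += list(rng.choice(matched, size=n_common_sel, replace=False)) if n_common_sel else []
        sel_rows = []
        for o in sel_ids:
            res = selection.zeta_lrt(sim.alignments[o], fitted_tree, ocr_id=o)
            sel_rows.append(dataclasses.asdict(res))
        sel = pd.DataFrame(sel_rows).set_index("ocr_id") if sel_rows else pd.DataFrame()
        if len(sel):
            sel["q_accel"] = diffacc.bh_adjust(sel["p_accel"].fillna(1.0))
            sel["group"] = calls.loc[sel.index, "state"]

        # ----------------------------------------------------------- motifs
        stage = "motifs"
        null_map = motifs.nearest_null_map(calls, atlas)
        motif_summary = _motif_stage(sim, calls, null_map, config)

        # ------------------------------------------------------------ truth
        confusion, fdp = None, None
        if sim.truth is not None:
            truth_states = sim.truth.table.loc[calls.index, "state"]
            confusion = pd.crosstab(
                truth_states, calls["state"], rownames=["truth"], colnames=["called"]
            )
            called_specific = calls["state"].isin(polarize.SPECIES_SPECIFIC_STATES)
            n_called = int(called_specific.sum())
            fdp = (
                float((truth_states[called_specific] == "common").mean())
                if n_called
                else 0.0
            )

        # ------------------------------------------------------------ write
        stage = "write"
        calls.to_csv(out / "states.tsv", sep="\t")
        state_table.to_csv(out / "state_counts.tsv", sep="\t", index=False)
        pd.Series(matched, name="ocr_id").to_csv(out / "matched_common.tsv", sep="\t", index=False)
        presence.to_csv(out / "presence.tsv", sep="\t")
        if len(enrichment):
            enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        if len(sel):
            sel.to_csv(out / "selection.tsv", sep="\t")
        pca_coords.to_csv(out / "pca.tsv", sep="\t")
        corr.to_csv(out / "replicate_correlations.tsv", sep="\t")
        if confusion is not None:
            confusion.to_csv(out / "confusion.tsv", sep="\t")
        report = RunReport(
            state_table=state_table,
            enrichment=enrichment,
            selection_summary=_selection_summary(sel),
            motif_summary=motif_summary,
            pca_variance=pca_var,
            confusion=confusion,
            empirical_fdp=fdp,
            outdir=out,
        )
        (out / "report.md").write_text(_render_report(report, pleio, expr, retained))
        return report
    except Exception:
        logger.error("pipeline failed at stage %r; partial outputs in %s", stage, out)
        raise


def _motif_stage(sim, calls, null_map, config: RunConfig) -> dict:
    pwms = sim.pwms
    nfia, pparg = pwms["NFIA"], pwms["PPARG"]
    out: dict = {}
    hd = [o for o in calls.index[calls["state"] == "human_decreased"] if o in sim.sequences]
    nulls = [
        null_map.at[o, "null_ocr_id"]
        for o in hd
        if o in null_map.index and null_map.at[o, "null_ocr_id"] is not None
    ]
    nulls = [n for n in nulls if isinstance(n, str) and n in sim.sequences]
    if not hd or not nulls:
        return {"note": "no human_decreased OCRs or no nearest nulls"}
    hd_seqs = {o: sim.sequences[o] for o in hd}
    null_seqs = {o: sim.sequences[o] for o in dict.fromkeys(nulls)}
    thr = config.pwm_threshold
    hd_nfia = motifs.best_hit_scores(hd_seqs, nfia, thr)
    null_nfia = motifs.best_hit_scores(null_seqs, nfia, thr)
    out["nfia_rate_human_decreased"] = float(hd_nfia["has_hit"].mean())
    out["nfia_rate_null"] = float(null_nfia["has_hit"].mean())
    if hd_nfia["has_hit"].any():
        rate, _ = motifs.cooccurrence_rate(hd_seqs, nfia, pparg, thr)
        out["nfia_pparg_cooccurrence"] = rate
    try:
        auc, _ = motifs.kmer_classify_auc(
            list(hd_seqs.values()), list(null_seqs.values()), seed=config.seed
        )
        out["kmer_auc_human_decreased_vs_null"] = auc
    except ValueError as e:  # too few sequences for CV
        out["kmer_auc_note"] = str(e)
    # ortholog motif-score comparison on the human/chimp alignment rows
    deltas = [
        motifs.ortholog_motif_delta(
            sim.alignments[o]["human"].replace("-", ""),
            sim.alignments[o]["chimp"].replace("-", ""),
            nfia,
            thr,
        )["delta"]
        for o in hd
        if o in sim.alignments
    ]
    out["mean_nfia_ortholog_delta"] = float(np.mean(deltas)) if deltas else np.nan
    return out


def _selection_summary(sel: pd.DataFrame) -> pd.DataFrame:
    if not len(sel):
        return pd.DataFrame()
    rows = []
    for group, sub in sel.groupby("group"):
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "median_zeta": float(sub["zeta_hat"].median()),
                "frac_accel_p05": float((sub["p_accel"] < 0.05).mean()),
                "frac_cons_p05": float((sub["p_cons"] < 0.05).mean()),
            }
        )
    return pd.DataFrame(rows)


def _render_report(report: RunReport, pleio: dict, expr: dict, retained: list[str]) -> str:
    lines = ["# primatlas run report", ""]
    lines += ["## Samples retained after QC", "", ", ".join(retained), ""]
    v = report.pca_variance
    lines += [
        "## PCA",
        "",
        f"PC1 {v[0] * 100:.1f}% and PC2 {v[1] * 100:.1f}% of variance." if len(v) > 1 else "",
        "",
        "## State counts",
        "",
        report.state_table.to_markdown(index=False),
        "",
    ]
    if len(report.enrichment):
        lines += ["## Enrichment vs matched common", "", report.enrichment.to_markdown(index=False), ""]
    if pleio:
        lines += ["## Pleiotropy (Fisher p vs matched common)", ""]
        lines += [f"- {g}: p = {d['p']:.3g} (k = {d['k']})" for g, d in pleio.items()]
        lines += [""]
    if expr:
        lines += ["## Expression association (rank-sum p; fraction near DE genes)", ""]
        lines += [
            f"- {g}: p = {d['p']:.3g}, near-DE fraction = {d['fraction_near_de']:.3f}"
            for g, d in expr.items()
        ]
        lines += [""]
    if len(report.selection_summary):
        lines += ["## Selection (zeta LRT)", "", report.selection_summary.to_markdown(index=False), ""]
    if report.motif_summary:
        lines += ["## Motifs", ""]
        lines += [f"- {k}: {v}" for k, v in report.motif_summary.items()]
        lines += [""]
    if report.confusion is not None:
        lines += [
            "## Truth evaluation",
            "",
            report.confusion.to_markdown(),
            "",
            f"Empirical FDP among species-specific calls: {report.empirical_fdp:.4f}",
            "",
        ]
    return "\n".join(lines)
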