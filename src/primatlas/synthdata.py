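"""Synthetic three-species ATAC-seq datasets with known ground truth.

The generator emulates the statistical structure the comparative
analysis assumes: a union atlas of 1:1:1 homologous open-chromatin
regions; negative-binomial read counts (Var = mu + alpha * mu^2) with
per-sample library size factors and the human 3 / chimp 2 / rhesus 1
biological-replicate design (technical replicates nested within);
branch-specific accessibility fold changes planted on a configurable
fraction of regions; region sequences with planted motif consensus
instances; per-region alignments evolved along a ((human,chimp),rhesus)
tree under JC69 with a foreground rate multiplier; and annotation
layers (promoter/enhancer/eQTL intervals, a tissue-openness matrix,
nearest-TSS genes with a differential-expression table) whose rates
depend on the true state. Everything is reproducible from a single
seed, and the planted truth is returned alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as pio
from .atlas import SPECIES
from .motifs import Pwm, builtin_pwms, reverse_complement
from .selection import PhyloTree, jc69_transition

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

DEFAULT_TREE = "((human:0.006,chimp:0.006):0.025,rhesus:0.03);"

# complete-vs-partial presence rates planted per species-specific state
DEFAULT_COMPLETE_RATE = {
    "human_increased": 0.895,
    "human_decreased": 0.551,
    "chimp_increased": 0.772,
    "chimp_decreased": 0.955,
}

# per-state probabilities that an OCR carries each annotation class
DEFAULT_ANNOTATION_RATE = {
    "promoter": {
        "common": 0.14, "ambiguous": 0.14,
        "human_decreased": 0.283, "chimp_decreased": 0.221,
        "human_increased": 0.052, "chimp_increased": 0.075,
    },
    "enhancer": {
        "common": 0.17, "ambiguous": 0.17,
        "human_decreased": 0.283, "chimp_decreased": 0.285,
        "human_increased": 0.115, "chimp_increased": 0.225,
    },
    "eqtl": {
        "common": 0.10, "ambiguous": 0.10,
        "human_decreased": 0.18, "chimp_decreased": 0.16,
        "human_increased": 0.10, "chimp_increased": 0.15,
    },
}

DEFAULT_MOTIF_PLANT_RATE = {
    "human_decreased": {"NFIA": 0.12, "PPARG": 0.75},
    "chimp_increased": {"NFIA": 0.10, "PPARG": 0.75},
    "common": {"NFIA": 0.08, "PPARG": 0.60},
}


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Replicate numbers default to the real study design (three human and
    two chimpanzee biological replicates, one rhesus, with technical
    replicates nested within each).
    """

    n_ocrs: int = 2000
    n_bio_reps: Mapping[str, int] = field(
        default_factory=lambda: {"human": 3, "chimp": 2, "rhesus": 1}
    )
    n_tech_reps: int = 2
    baseline_log_mean: float = 6.0  # log2 of expected counts at size factor 1
    baseline_log_sd: float = 1.5
    dispersion_alpha: float = 0.1  # Var = mu + alpha * mu^2
    frac_state_changed: Mapping[str, float] = field(
        default_factory=lambda: {
            "human_increased": 0.025,
            "human_decreased": 0.025,
            "chimp_increased": 0.025,
            "chimp_decreased": 0.025,
        }
    )
    planted_fold: float = 4.0
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seq_length: int = 300
    gc_content: float = 0.5
    motif_plant_rate: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            state: dict(rates) for state, rates in DEFAULT_MOTIF_PLANT_RATE.items()
        }
    )
    tree_newick: str = DEFAULT_TREE
    foreground: str = "human"
    planted_zeta: float = 1.0
    complete_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLETE_RATE)
    )
    annotation_rate: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_ANNOTATION_RATE.items()
        }
    )
    n_tissues: int = 10
    ocrs_per_chrom: int = 200
    seed: int = 0

    def validate(self, pwms: Mapping[str, Pwm] | None = None) -> None:
        if self.n_ocrs <= 0:
            raise ValueError("n_ocrs must be positive")
        total = sum(self.frac_state_changed.values())
        if not all(0 <= f <= 1 for f in self.frac_state_changed.values()) or total > 1:
            raise ValueError("state fractions must be in [0,1] and sum to <= 1")
        if self.planted_fold < 1:
            raise ValueError("planted_fold must be >= 1")
        if self.planted_zeta < 0:
            raise ValueError("planted_zeta must be >= 0")
        if pwms:
            longest = max(p.length for p in pwms.values())
            if self.seq_length < longest:
                raise ValueError(
                    f"seq_length {self.seq_length} < longest PWM ({longest} bp)"
                )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["size_factor_range"] = list(self.size_factor_range)
        return json.dumps(d, indent=2)


@dataclass
class TruthTable:
    """Planted ground truth: per-OCR state/fold/motifs/zeta and the
    per-sample true size factors."""

    table: pd.DataFrame
    size_factors: pd.Series


@dataclass
class SimResult:
    atlas: pd.DataFrame
    counts: pd.DataFrame
    meta: pd.DataFrame
    sequences: dict[str, str]
    alignments: dict[str, dict[str, str]]
    peak_sets: dict[str, pd.DataFrame]
    ortholog_map: pd.DataFrame
    annotations: dict
    truth: TruthTable
    tree: PhyloTree
    pwms: dict[str, Pwm]
    config: SimConfig


def sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for sp in SPECIES:
        for b in range(1, config.n_bio_reps.get(sp, 1) + 1):
            for t in range(1, config.n_tech_reps + 1):
                rows.append((f"{sp}_b{b}t{t}", sp, b, t))
    meta = pd.DataFrame(rows, columns=["sample_id", "species", "bio_rep", "tech_rep"])
    return meta.set_index("sample_id", drop=False)


def _make_atlas(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lengths = np.clip(
        np.exp(rng.normal(np.log(400), 0.4, size=config.n_ocrs)), 150, 3000
    ).astype(int)
    gaps = rng.integers(2000, 8000, size=config.n_ocrs)
    rows = []
    pos, chrom_i, on_chrom = 10_000, 1, 0
    for i in range(config.n_ocrs):
        if on_chrom >= config.ocrs_per_chrom:
            chrom_i += 1
            on_chrom = 0
            pos = 10_000
        start = pos
        end = start + lengths[i]
        rows.append((f"chr{chrom_i}", start, end))
        pos = end + gaps[i]
        on_chrom += 1
    atlas = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    atlas.insert(0, "ocr_id", [f"ocr_{i:06d}" for i in range(len(atlas))])
    # native frames: same chromosome names, species-specific coordinate shift
    for k, sp in enumerate(SPECIES):
        atlas[f"{sp}_chrom"] = atlas["chrom"]
        atlas[f"{sp}_start"] = atlas["start"] + k * 17
        atlas[f"{sp}_end"] = atlas["end"] + k * 17
    return atlas.set_index("ocr_id", drop=False)


def _ortholog_map(atlas: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sp in SPECIES:
        for _, r in atlas.iterrows():
            rows.append(
                (
                    r["chrom"], r["start"], r["end"], sp,
                    r[f"{sp}_chrom"], r[f"{sp}_start"], r[f"{sp}_end"],
                )
            )
    return pd.DataFrame(rows, columns=list(pio.ORTHOLOG_MAP_COLUMNS))


def _assign_states(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    states = np.full(config.n_ocrs, "common", dtype=object)
    order = rng.permutation(config.n_ocrs)
    cursor = 0
    for state, frac in config.frac_state_changed.items():
        n = int(round(frac * config.n_ocrs))
        states[order[cursor : cursor + n]] = state
        cursor += n
    return states


def simulate_counts(
    truth: TruthTable, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """NB counts: count_ij ~ NB(mean = s_j * q_i * f_(species(j), i), alpha).

    alpha = 0 gives the Poisson limit."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = truth.table
    meta = sample_table(config)
    s = truth.size_factors.loc[meta.index].to_numpy()
    q = t["baseline"].to_numpy()[:, None]
    fold = np.ones((len(t), len(meta)))
    for j, sp in enumerate(meta["species"]):
        inc = t["state"] == f"{sp}_increased"
        dec = t["state"] == f"{sp}_decreased"
        fold[inc.to_numpy(), j] = t.loc[inc, "fold"]
        fold[dec.to_numpy(), j] = 1.0 / t.loc[dec, "fold"]
    mu = s[None, :] * q * fold
    alpha = config.dispersion_alpha
    if alpha <= 0:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
    return pd.DataFrame(counts, index=t.index, columns=meta.index)


def _random_sequences(
    n: int, length: int, gc: float, rng: np.random.Generator
) -> list[str]:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=(n, length), p=probs)
    return ["".join(_BASES[row]) for row in draws]


def simulate_sequences_with_motifs(
    truth: TruthTable,
    pwms: Mapping[str, Pwm],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """i.i.d. background sequences with PWM consensus instances embedded
    at recorded positions/strands, per the configured per-state rates.

    Returns (sequences, plant log with ocr_id, pwm, position, strand)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    for name, p in pwms.items():
        if p.length > config.seq_length:
            raise ValueError(f"seq_length < PWM {name} length")
    t = truth.table
    seqs = dict(zip(t.index, _random_sequences(len(t), config.seq_length, config.gc_content, rng)))
    plants = []
    for ocr, state in zip(t.index, t["state"]):
        rates = config.motif_plant_rate.get(state, {})
        for pwm_name, rate in rates.items():
            if rng.random() >= rate:
                continue
            pwm = pwms[pwm_name]
            pos = int(rng.integers(0, config.seq_length - pwm.length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            ins = pwm.consensus if strand == "+" else reverse_complement(pwm.consensus)
            s = seqs[ocr]
            seqs[ocr] = s[:pos] + ins + s[pos + pwm.length :]
            plants.append((ocr, pwm_name, pos, strand))
    log = pd.DataFrame(plants, columns=["ocr_id", "pwm", "position", "strand"])
    return seqs, log


def _evolve(seq_codes: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    if t <= 0:
        return seq_codes.copy()
    P = jc69_transition(t)
    cum = P.cumsum(axis=1)
    u = rng.random(seq_codes.shape[0])
    return (u[:, None] > cum[seq_codes]).sum(axis=1).astype(np.int8)


def simulate_alignments(
    tree: PhyloTree,
    truth: TruthTable,
    config: SimConfig,
    sequences: Mapping[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, str]]:
    """Per-OCR leaf alignments evolved site-independently down the tree
    under JC69; the foreground branch length is multiplied by the OCR's
    true zeta. Root sequences are the reference-frame OCR sequences when
    given, else drawn from the stationary (uniform) base frequencies."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if np.any(tree.edge_len < 0):
        raise ValueError("negative branch length")
    t = truth.table
    base_to_code = {b: i for i, b in enumerate("ACGT")}
    out: dict[str, dict[str, str]] = {}
    order = [i for i in range(tree.n_nodes)][::-1]  # preorder: root first
    for ocr, zeta in zip(t.index, t["zeta"]):
        if sequences is not None:
            root = np.array([base_to_code.get(b, 0) for b in sequences[ocr]], dtype=np.int8)
        else:
            root = rng.integers(0, 4, size=config.seq_length).astype(np.int8)
        node_seq: dict[int, np.ndarray] = {tree.root: root}
        for i in order:
            if i == tree.root:
                continue
            scale = zeta if i == tree.foreground_node else 1.0
            node_seq[i] = _evolve(node_seq[tree.parent[i]], tree.edge_len[i] * scale, rng)
        out[ocr] = {
            name: "".join(_BASES[node_seq[idx]]) for name, idx in tree.leaf_index.items()
        }
    return out


def _simulate_presence(
    truth: TruthTable, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    t = truth.table
    pres = pd.DataFrame(True, index=t.index, columns=list(SPECIES))
    others = {"human": ["chimp", "rhesus"], "chimp": ["human", "rhesus"]}
    for ocr, state in zip(t.index, t["state"]):
        if state == "common":
            continue
        focal, direction = state.split("_")
        complete = rng.random() < config.complete_rate.get(state, 0.8)
        if direction == "increased":
            if complete:
                for o in others[focal]:
                    pres.at[ocr, o] = False
            else:
                pres.at[ocr, others[focal][int(rng.integers(0, 2))]] = False
        else:
            pres.at[ocr, focal] = not complete
    return pres


def _peak_sets(
    atlas: pd.DataFrame, presence: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    out = {}
    for sp in SPECIES:
        sel = atlas.loc[presence[sp]]
        out[sp] = pd.DataFrame(
            {
                "chrom": sel[f"{sp}_chrom"].to_numpy(),
                "start": sel[f"{sp}_start"].to_numpy(),
                "end": sel[f"{sp}_end"].to_numpy(),
            }
        ).sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


def _annotations(
    atlas: pd.DataFrame,
    truth: TruthTable,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict:
    t = truth.table
    beds = {}
    for annot, rates in config.annotation_rate.items():
        rows = []
        for ocr, state in zip(t.index, t["state"]):
            if rng.random() < rates.get(state, 0.1):
                start = atlas.at[ocr, "start"]
                end = atlas.at[ocr, "end"]
                mid = (start + end) // 2
                rows.append((atlas.at[ocr, "chrom"], max(start, mid - 50), min(end, mid + 50)))
        beds[annot] = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    # tissue-openness: decreased states are planted as more pleiotropic
    p_open = np.where(
        t["state"].str.endswith("decreased"), 0.6,
        np.where(t["state"].str.endswith("increased"), 0.3, 0.4),
    )
    tissue = pd.DataFrame(
        rng.random((len(t), config.n_tissues)) < p_open[:, None],
        index=t.index,
        columns=[f"tissue_{i}" for i in range(config.n_tissues)],
    )

    # one gene per OCR neighborhood; species-specific OCRs sit slightly
    # closer to differentially expressed genes
    genes, tss_rows, de_rows = [], [], []
    for i, (ocr, state) in enumerate(zip(t.index, t["state"])):
        gene = f"gene_{i:06d}"
        genes.append(gene)
        offset = int(rng.integers(-2000, 2000))
        pos = max(0, atlas.at[ocr, "start"] + offset)
        tss_rows.append((atlas.at[ocr, "chrom"], pos, pos + 1, gene))
        de_rate = 0.05 if state in ("common", "ambiguous") else 0.08
        is_de = rng.random() < de_rate
        lfc = rng.normal(0, 2.0) if is_de else rng.normal(0, 0.3)
        q = rng.uniform(0, 0.05) if is_de else rng.uniform(0.05, 1.0)
        de_rows.append((gene, lfc, q))
    tss = pd.DataFrame(tss_rows, columns=["chrom", "start", "end", "name"])
    de = pd.DataFrame(de_rows, columns=["gene", "log2fc", "q"])
    return {"beds": beds, "tissue_open": tissue, "tss": tss, "de_table": de}


def corrupt_replicate(
    counts: pd.DataFrame, sample_id: str, noise_level: float, seed: int = 0
) -> pd.DataFrame:
    """Return a copy with one sample's counts partially shuffled across
    OCRs, reducing its correlation with its replicates; noise_level is
    the fraction of rows whose values are permuted (0 = unchanged).
    All other columns are untouched."""
    if sample_id not in counts.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    if not 0 <= noise_level <= 1:
        raise ValueError("noise_level must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = counts.copy()
    n = int(round(noise_level * len(counts)))
    if n < 2:
        return out
    rows = rng.choice(len(counts), size=n, replace=False)
    vals = out.iloc[rows, out.columns.get_loc(sample_id)].to_numpy()
    out.iloc[rows, out.columns.get_loc(sample_id)] = rng.permutation(vals)
    return out


def simulate_dataset(config: SimConfig, pwms: Mapping[str, Pwm] | None = None) -> SimResult:
    """Generate one complete, mutually consistent synthetic dataset."""
    if pwms is None:
        pwms = builtin_pwms()
    config.validate(pwms)
    rng = np.random.default_rng(config.seed)

    atlas = _make_atlas(config, rng)
    meta = sample_table(config)
    states = _assign_states(config, rng)
    baseline = 2.0 ** rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_ocrs)
    zeta = np.where(
        np.isin(states, [f"{config.foreground}_increased", f"{config.foreground}_decreased"]),
        config.planted_zeta,
        1.0,
    )
    size = pd.Series(
        rng.uniform(*config.size_factor_range, size=len(meta)),
        index=meta.index,
        name="size_factor",
    )
    table = pd.DataFrame(
        {
            "state": states,
            "fold": np.where(states == "common", 1.0, config.planted_fold),
            "baseline": baseline,
            "zeta": zeta,
        },
        index=atlas.index,
    )
    truth = TruthTable(table=table, size_factors=size)

    counts = simulate_counts(truth, config, rng)
    sequences, plant_log = simulate_sequences_with_motifs(truth, pwms, config, rng)
    tree = PhyloTree(config.tree_newick, foreground=config.foreground)
    alignments = simulate_alignments(tree, truth, config, sequences, rng)
    presence_truth = _simulate_presence(truth, config, rng)
    peak_sets = _peak_sets(atlas, presence_truth)
    omap = _ortholog_map(atlas)
    annotations = _annotations(atlas, truth, config, rng)

    for pwm_name in pwms:
        planted = set(plant_log.loc[plant_log["pwm"] == pwm_name, "ocr_id"])
        truth.table[f"motif_{pwm_name}"] = [o in planted for o in truth.table.index]
    truth.table["presence_" + "".join(s[0] for s in SPECIES)] = [
        "".join("T" if presence_truth.at[o, sp] else "F" for sp in SPECIES)
        for o in truth.table.index
    ]
    annotations["plant_log"] = plant_log
    annotations["presence_truth"] = presence_truth
    return SimResult(
        atlas=atlas,
        counts=counts,
        meta=meta,
        sequences=sequences,
        alignments=alignments,
        peak_sets=peak_sets,
        ortholog_map=omap,
        annotations=annotations,
        truth=truth,
        tree=tree,
        pwms=pwms,
        config=config,
    )


def write_dataset(sim: SimResult, outdir) -> None:
    """Write every component as plain text (BED/TSV/FASTA/newick/JSON)."""
    out = pio.ensure_dir(outdir)
    pio.write_bed(sim.atlas, out / "atlas.bed", extra_cols=["ocr_id"])
    pio.write_counts(sim.counts, out / "counts.tsv")
    sim.meta.to_csv(out / "meta.tsv", sep="\t", index=False)
    for sp, peaks in sim.peak_sets.items():
        pio.write_bed(peaks, out / f"peaks_{sp}.bed")
    sim.ortholog_map.to_csv(out / "ortholog_map.tsv", sep="\t", index=False)
    pio.write_fasta(sim.sequences, out / "sequences.fa")
    aln_dir = pio.ensure_dir(out / "alignments")
    for ocr, aln in sim.alignments.items():
        pio.write_fasta(aln, aln_dir / f"{ocr}.fa")
    (out / "tree.nwk").write_text(sim.config.tree_newick + "\n")
    for annot, bed in sim.annotations["beds"].items():
        pio.write_bed(bed, out / f"{annot}.bed")
    sim.annotations["tissue_open"].astype(int).to_csv(out / "tissue_open.tsv", sep="\t")
    pio.write_bed(sim.annotations["tss"], out / "tss.bed", extra_cols=["name"])
    sim.annotations["de_table"].to_csv(out / "de_table.tsv", sep="\t", index=False)
    sim.truth.table.to_csv(out / "truth.tsv", sep="\t")
    sim.truth.size_factors.to_csv(out / "true_size_factors.tsv", sep="\t")
    (out / "sim_config.json").write_text(sim.config.to_json() + "\n")
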