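"""Union open-chromatin atlas with 1:1:1 cross-species homology.

Per-species peak calls live in each species' native genome frame. An
explicit ortholog interval map relates native segments to a shared
reference frame; peaks are projected through it, the projections are
merged into a union set, and only regions with a homologous segment in
every species are kept. Downstream stages then work entirely in the
reference frame.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("human", "chimp", "rhesus")


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Single-linkage merge of half-open intervals sharing >= 1 bp.

    Bookended intervals (end == next start) are NOT merged.
    """
    if df.empty:
        return df.loc[:, ["chrom", "start", "end"]].copy()
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    out = []
    cur_chrom, cur_start, cur_end = None, None, None
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if chrom == cur_chrom and start < cur_end:
            cur_end = max(cur_end, end)
        else:
            if cur_chrom is not None:
                out.append((cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = chrom, start, end
    out.append((cur_chrom, cur_start, cur_end))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _overlap_mask(
    query: pd.DataFrame, subject: pd.DataFrame, qcols=("chrom", "start", "end"),
    scols=("chrom", "start", "end"),
) -> np.ndarray:
    """Boolean per query row: does it overlap any subject interval by >= 1 bp?"""
    mask = np.zeros(len(query), dtype=bool)
    if query.empty or subject.empty:
        return mask
    for chrom, sub in subject.groupby(scols[0]):
        sel = query[qcols[0]] == chrom
        if not sel.any():
            continue
        starts = np.sort(sub[scols[1]].to_numpy())
        # for each subject start, the max end among subjects starting <= it
        order = np.argsort(sub[scols[1]].to_numpy(), kind="stable")
        ends_sorted = sub[scols[2]].to_numpy()[order]
        cummax_end = np.maximum.accumulate(ends_sorted)
        qs = query.loc[sel, qcols[1]].to_numpy()
        qe = query.loc[sel, qcols[2]].to_numpy()
        # overlap iff some subject with start < qe has end > qs
        idx = np.searchsorted(starts, qe, side="left") - 1
        hit = (idx >= 0) & (np.where(idx >= 0, cummax_end[np.clip(idx, 0, None)], 0) > qs)
        mask[np.flatnonzero(sel.to_numpy())] = hit
    return mask


def _reject_ambiguous_rows(omap: pd.DataFrame) -> pd.DataFrame:
    """Drop map rows whose reference intervals overlap another row of the
    same species (many-to-one correspondences); rejections are logged."""
    keep = np.ones(len(omap), dtype=bool)
    omap = omap.reset_index(drop=True)
    for species, sub in omap.groupby("species"):
        sub = sub.sort_values(["ref_chrom", "ref_start"])
        idx = sub.index.to_numpy()
        chroms = sub["ref_chrom"].to_numpy()
        starts = sub["ref_start"].to_numpy()
        ends = sub["ref_end"].to_numpy()
        for i in range(1, len(sub)):
            if chroms[i] == chroms[i - 1] and starts[i] < ends[i - 1]:
                keep[idx[i]] = False
                keep[idx[i - 1]] = False
    n_rejected = int((~keep).sum())
    if n_rejected:
        logger.warning("rejected %d ambiguous ortholog-map rows", n_rejected)
    return omap.loc[keep]


def project_peaks(peaks: pd.DataFrame, omap: pd.DataFrame, species: str) -> pd.DataFrame:
    """Project native-frame peaks into the reference frame.

    A peak maps to the reference interval of every ortholog segment it
    overlaps in the native frame; peaks overlapping no segment are dropped.
    """
    sub = omap[omap["species"] == species]
    if sub.empty or peaks.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = []
    for chrom, seg in sub.groupby("native_chrom"):
        p = peaks[peaks["chrom"] == chrom]
        if p.empty:
            continue
        for ps, pe in zip(p["start"], p["end"]):
            hit = seg[(seg["native_start"] < pe) & (seg["native_end"] > ps)]
            for _, row in hit.iterrows():
                out.append((row["ref_chrom"], row["ref_start"], row["ref_end"]))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def build_union_atlas(
    peak_sets: Mapping[str, pd.DataFrame],
    ortholog_map: pd.DataFrame,
    species: tuple[str, ...] = SPECIES,
) -> pd.DataFrame:
    """Union OCR atlas over all species' projected peaks, restricted to
    regions with 1:1:1 homology.

    Returns a DataFrame sorted by (chrom, start) with reference
    coordinates, one native interval per species, and stable ocr ids.
    """
    omap = _reject_ambiguous_rows(ortholog_map)
    projected = pd.concat(
        [project_peaks(peak_sets[sp], omap, sp) for sp in species],
        ignore_index=True,
    )
    merged = merge_intervals(projected)
    logger.info("union of projected peaks: %d raw, %d merged", len(projected), len(merged))

    # 1:1:1 requirement: every species must have a homologous segment here
    native_cols: dict[str, list] = {}
    keep = np.ones(len(merged), dtype=bool)
    for sp in species:
        seg = omap[omap["species"] == sp]
        rows = []
        for i, (chrom, start, end) in enumerate(
            zip(merged["chrom"], merged["start"], merged["end"])
        ):
            hit = seg[
                (seg["ref_chrom"] == chrom)
                & (seg["ref_start"] < end)
                & (seg["ref_end"] > start)
            ]
            if hit.empty or hit["native_chrom"].nunique() > 1:
                keep[i] = False
                rows.append((None, -1, -1))
            else:
                rows.append(
                    (
                        hit["native_chrom"].iloc[0],
                        int(hit["native_start"].min()),
                        int(hit["native_end"].max()),
                    )
                )
        native_cols[sp] = rows
    atlas = merged.copy()
    for sp in species:
        atlas[f"{sp}_chrom"] = [r[0] for r in native_cols[sp]]
        atlas[f"{sp}_start"] = [r[1] for r in native_cols[sp]]
        atlas[f"{sp}_end"] = [r[2] for r in native_cols[sp]]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d merged OCRs lacking 1:1:1 homology", n_dropped)
    atlas = atlas.loc[keep].sort_values(["chrom", "start"]).reset_index(drop=True)
    atlas.insert(0, "ocr_id", [f"ocr_{i:06d}" for i in range(len(atlas))])
    return atlas.set_index("ocr_id", drop=False)


def filter_zero_count(atlas: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    """Drop any OCR with a zero count in any sample (a mapping-artifact
    guard); idempotent."""
    extra = counts.index.difference(atlas.index)
    if len(extra):
        raise ValueError(
            f"{len(extra)} OCRs present in counts but missing from atlas"
        )
    missing = atlas.index.difference(counts.index)
    if len(missing):
        raise ValueError(f"{len(missing)} atlas OCRs missing from counts")
    ok = (counts.loc[atlas.index] >= 1).all(axis=1)
    n_removed = int((~ok).sum())
    if n_removed:
        logger.info("zero-count filter removed %d of %d OCRs", n_removed, len(atlas))
    return atlas.loc[ok[ok].index]


def binary_presence(
    atlas: pd.DataFrame,
    peak_sets: Mapping[str, pd.DataFrame],
    ortholog_map: pd.DataFrame,
    species: tuple[str, ...] = SPECIES,
) -> pd.DataFrame:
    """Presence/absence of a called peak over each OCR, per species.

    presence[i, s] is True iff species s has a peak whose reference-frame
    projection overlaps OCR i by >= 1 bp.
    """
    omap = _reject_ambiguous_rows(ortholog_map)
    out = pd.DataFrame(index=atlas.index)
    for sp in species:
        proj = project_peaks(peak_sets[sp], omap, sp)
        out[sp] = _overlap_mask(atlas, proj)
    return out


def assign_closest_tss(atlas: pd.DataFrame, tss: pd.DataFrame) -> pd.DataFrame:
    """Closest TSS per OCR, by distance from the OCR midpoint.

    A TSS inside the OCR counts as distance 0. Ties go to the
    lexicographically smaller gene id. Chromosomes without any TSS yield
    a missing assignment (logged). Returns columns gene, distance
    (signed, TSS minus midpoint; 0 when contained) and abs_distance.
    """
    if "name" not in tss.columns:
        raise ValueError("TSS BED must carry gene ids in the name field")
    genes, dists = [], []
    by_chrom = {
        chrom: sub.sort_values(["start", "name"]).reset_index(drop=True)
        for chrom, sub in tss.groupby("chrom")
    }
    n_missing = 0
    for chrom, start, end in zip(atlas["chrom"], atlas["start"], atlas["end"]):
        sub = by_chrom.get(chrom)
        if sub is None or sub.empty:
            genes.append(None)
            dists.append(np.nan)
            n_missing += 1
            continue
        pos = sub["start"].to_numpy()
        mid = (start + end) // 2
        inside = (pos >= start) & (pos < end)
        if inside.any():
            genes.append(min(sub.loc[inside, "name"]))
            dists.append(0)
            continue
        d = np.abs(pos - mid)
        best = d.min()
        cand = sub.loc[d == best, ["name", "start"]]
        row = cand.sort_values("name").iloc[0]
        genes.append(row["name"])
        dists.append(int(row["start"] - mid))
    if n_missing:
        logger.warning("%d OCRs on chromosomes without any TSS", n_missing)
    out = pd.DataFrame(
        {"gene": genes, "distance": dists}, index=atlas.index
    )
    out["abs_distance"] = out["distance"].abs()
    return out
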