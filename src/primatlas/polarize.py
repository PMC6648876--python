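"""Outgroup polarization of accessibility changes.

With rhesus macaque as the outgroup, a human-chimp difference is
assigned to the branch on which it arose: a change is human-specific
when human differs from rhesus while chimp does not (and symmetrically
for chimp). Species-specific calls additionally require at least a
2-fold human-chimp difference. OCRs with a significant species effect
matching no single-branch pattern are left ambiguous.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATES = (
    "common",
    "human_increased",
    "human_decreased",
    "chimp_increased",
    "chimp_decreased",
    "ambiguous",
)
SPECIES_SPECIFIC_STATES = STATES[1:5]


def classify_states(
    species_effect: pd.DataFrame,
    hc: pd.DataFrame,
    hr: pd.DataFrame,
    cr: pd.DataFrame,
    fdr: float = 0.05,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-OCR state calls from the species-effect test and the three
    pairwise contrasts (hc: human vs chimp, hr: human vs rhesus,
    cr: chimp vs rhesus).

    Rules: common iff species-effect q >= fdr. Otherwise a branch call
    needs (i) focal-vs-rhesus q < fdr with the matching sign, (ii) the
    other branch's contrast with rhesus NOT significant, and (iii)
    |human-chimp log2FC| >= log2(fc_threshold) in the matching
    direction. Everything else is ambiguous.
    """
    for name, df in (("human-chimp", hc), ("human-rhesus", hr), ("chimp-rhesus", cr)):
        if df is None or not {"log2fc", "q"}.issubset(df.columns):
            raise ValueError(f"missing or incomplete contrast: {name}")
    idx = species_effect.index
    lfc_min = np.log2(fc_threshold)
    hr_sig = hr["q"].to_numpy() < fdr
    cr_sig = cr["q"].to_numpy() < fdr
    hr_up = hr["log2fc"].to_numpy() > 0
    cr_up = cr["log2fc"].to_numpy() > 0
    hc_fc = hc["log2fc"].to_numpy()

    state = np.full(len(idx), "ambiguous", dtype=object)
    common = species_effect["q"].to_numpy() >= fdr
    state[common] = "common"

    human_inc = ~common & hr_sig & hr_up & ~cr_sig & (hc_fc >= lfc_min)
    human_dec = ~common & hr_sig & ~hr_up & ~cr_sig & (hc_fc <= -lfc_min)
    chimp_inc = ~common & cr_sig & cr_up & ~hr_sig & (hc_fc <= -lfc_min)
    chimp_dec = ~common & cr_sig & ~cr_up & ~hr_sig & (hc_fc >= lfc_min)
    state[human_inc] = "human_increased"
    state[human_dec] = "human_decreased"
    state[chimp_inc] = "chimp_increased"
    state[chimp_dec] = "chimp_decreased"

    calls = pd.DataFrame(
        {
            "state": state,
            "completeness": "not_applicable",
            "species_q": species_effect["q"].to_numpy(),
            "hr_q": hr["q"].to_numpy(),
            "cr_q": cr["q"].to_numpy(),
            "hc_log2fc": hc_fc,
        },
        index=idx,
    )
    counts = calls["state"].value_counts()
    logger.info("state calls: %s", counts.to_dict())
    return calls


def matched_common_set(
    state_calls: pd.DataFrame,
    norm_counts: pd.DataFrame,
    atlas: pd.DataFrame,
    lo: float = 20.0,
    hi: float = 80.0,
) -> list[str]:
    """Common OCRs matched to the species-specific set on intensity and size.

    A common OCR is kept iff its mean normalized count lies within the
    [lo, hi] percentile window (inclusive, linear-interpolation
    percentiles) of the species-specific OCRs' mean normalized counts,
    AND its length lies within the same percentile window of the
    species-specific lengths.
    """
    specific = state_calls.index[state_calls["state"].isin(SPECIES_SPECIFIC_STATES)]
    if len(specific) == 0:
        raise ValueError("no species-specific OCRs to match against")
    common = state_calls.index[state_calls["state"] == "common"]
    mean_counts = norm_counts.mean(axis=1)
    lengths = (atlas["end"] - atlas["start"]).astype(float)

    ref_counts = mean_counts.loc[specific].to_numpy()
    ref_lengths = lengths.loc[specific].to_numpy()
    c_lo, c_hi = np.percentile(ref_counts, [lo, hi])
    l_lo, l_hi = np.percentile(ref_lengths, [lo, hi])

    cvals = mean_counts.loc[common]
    lvals = lengths.loc[common]
    ok = (cvals >= c_lo) & (cvals <= c_hi) & (lvals >= l_lo) & (lvals <= l_hi)
    matched = list(common[ok.to_numpy()])
    logger.info(
        "matched common set: %d of %d common OCRs inside count window "
        "[%.2f, %.2f] and length window [%.1f, %.1f]",
        len(matched), len(common), c_lo, c_hi, l_lo, l_hi,
    )
    return matched


def completeness_labels(
    state_calls: pd.DataFrame, presence: pd.DataFrame
) -> pd.DataFrame:
    """Fill complete/partial labels from binary peak presence.

    Increased states: a complete gain has no called peak in either other
    species. Decreased states: a complete loss has no called peak in the
    focal species. All other species-specific calls are partial.
    """
    out = state_calls.copy()
    labels = out["completeness"].to_numpy(dtype=object)
    pres = presence.loc[out.index]
    others = {"human": ("chimp", "rhesus"), "chimp": ("human", "rhesus")}
    for i, (ocr, state) in enumerate(zip(out.index, out["state"])):
        if state not in SPECIES_SPECIFIC_STATES:
            labels[i] = "not_applicable"
            continue
        focal, direction = state.split("_")
        if direction == "increased":
            o1, o2 = others[focal]
            labels[i] = "complete" if not (pres.at[ocr, o1] or pres.at[ocr, o2]) else "partial"
        else:
            labels[i] = "complete" if not pres.at[ocr, focal] else "partial"
    out["completeness"] = labels
    return out


def state_count_table(state_calls: pd.DataFrame, matched: list[str] | None = None) -> pd.DataFrame:
    """Summary table of state-group sizes (total, matched common, four
    species-specific groups, ambiguous)."""
    rows = [("total", len(state_calls))]
    if matched is not None:
        rows.append(("common_matched", len(matched)))
    for s in SPECIES_SPECIFIC_STATES + ("common", "ambiguous"):
        rows.append((s, int((state_calls["state"] == s).sum())))
    return pd.DataFrame(rows, columns=["group", "n"])
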