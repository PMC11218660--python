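"""REF/ALT and wild-type/mutant differential activity.

Pairs are compared with a paired two-sided t-test on per-replicate activity
differences (ALT minus REF), BH-adjusted across the whole experiment.  A
pair is called MPRA-DA (variant decreased activity) when
log2FC <= -0.58, MPRA-IA when log2FC >= 0.58 — in both cases requiring
padj < 0.05 and detectable activity in at least one pair member — and
MPRA-NS otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2FC_CUTOFF = 0.58   # |log2 FC| >= 0.58, i.e. 1.5-fold
PADJ_CUTOFF = 0.05
MIN_PAIRED_REPLICATES = 3


def pair_test(ref_activity: np.ndarray, alt_activity: np.ndarray
              ) -> tuple[float, float, float, bool]:
    """Paired t-test on per-replicate activity differences.

    Returns (log2fc, t, p, undertested).  log2fc is the mean of the
    per-replicate ALT - REF differences.  With fewer than three complete
    replicate pairs the test is flagged undertested and p set to 1.
    Zero-variance nonzero differences give p = 0 without numeric failure.
    """
    ref = np.asarray(ref_activity, float)
    alt = np.asarray(alt_activity, float)
    ok = np.isfinite(ref) & np.isfinite(alt)
    ref, alt = ref[ok], alt[ok]
    d = alt - ref
    log2fc = float(d.mean()) if len(d) else 0.0
    if len(d) < MIN_PAIRED_REPLICATES:
        return log2fc, 0.0, 1.0, True
    sd = d.std(ddof=1)
    if sd == 0.0:
        if log2fc == 0.0:
            return 0.0, 0.0, 1.0, False
        return log2fc, np.sign(log2fc) * np.inf, 0.0, False
    t = log2fc / (sd / np.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), df=len(d) - 1)
    return log2fc, float(t), float(p), False


def classify_pairs(pairs: pd.DataFrame, activity: pd.DataFrame,
                   active_calls: pd.DataFrame | None = None,
                   detectable: str = "active_call",
                   log2fc_cutoff: float = LOG2FC_CUTOFF,
                   padj_cutoff: float = PADJ_CUTOFF) -> pd.DataFrame:
    """Test and classify every REF/ALT pair.

    ``pairs`` needs columns pair_id, ref_id, alt_id; ``activity`` is the
    quantify-module table (design_id + activity_rep columns).  The
    "detectable activity in at least one sample" gate follows
    ``detectable``: ``"active_call"`` requires >= 1 pair member among the
    active calls; ``"nonzero_rna"`` only requires a member with positive
    mean activity.  BH is applied jointly across all tested pairs.
    """
    act = activity.set_index("design_id")
    rep_cols = [c for c in act.columns if c.startswith("activity_rep")]
    active_ids: set[str] = set()
    if active_calls is not None:
        active_ids = set(active_calls.loc[active_calls["active"], "design_id"])

    rows = []
    for _, pr in pairs.iterrows():
        missing = [i for i in (pr["ref_id"], pr["alt_id"]) if i not in act.index]
        if missing:
            rows.append((pr["pair_id"], pr["ref_id"], pr["alt_id"], 0.0, 0.0,
                         1.0, 0, True))
            continue
        ref = act.loc[pr["ref_id"], rep_cols].to_numpy(float)
        alt = act.loc[pr["alt_id"], rep_cols].to_numpy(float)
        log2fc, t, p, under = pair_test(ref, alt)
        if detectable == "active_call":
            n_act = sum(i in active_ids for i in (pr["ref_id"], pr["alt_id"]))
        elif detectable == "nonzero_rna":
            n_act = int(np.nanmean(ref) > 0) + int(np.nanmean(alt) > 0)
        else:
            raise ValueError(f"unknown detectable rule {detectable!r}")
        rows.append((pr["pair_id"], pr["ref_id"], pr["alt_id"], log2fc, t, p,
                     n_act, under))
    out = pd.DataFrame(rows, columns=["pair_id", "ref_id", "alt_id", "log2fc",
                                      "t", "p", "n_active_members", "undertested"])
    out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
    sig = (out["padj"] < padj_cutoff) & (out["n_active_members"] >= 1) \
        & ~out["undertested"]
    out["class"] = "MPRA-NS"
    out.loc[sig & (out["log2fc"] <= -log2fc_cutoff), "class"] = "MPRA-DA"
    out.loc[sig & (out["log2fc"] >= log2fc_cutoff), "class"] = "MPRA-IA"
    return out


def summarize_classes(classed: pd.DataFrame,
                      participants: pd.Series | None = None) -> dict:
    """Counts per class and, when a pair -> participant map is given,
    per-participant tallies of non-NS calls."""
    summary = {"counts": classed["class"].value_counts().to_dict()}
    if participants is not None:
        hits = classed[classed["class"] != "MPRA-NS"]["pair_id"].map(participants)
        summary["per_participant"] = hits.value_counts().to_dict()
    return summary


def tiling_summary(classed: pd.DataFrame, activity: pd.DataFrame,
                   designs: pd.DataFrame) -> pd.DataFrame:
    """Per-fragment deletion-effect map for the tiling mutagenesis library.

    ``designs`` is the design manifest (design_id, role, pair_id,
    deletion_offset).  Fragments without a covered wild-type member are
    dropped entirely.  Returns one row per fragment with its WT activity and
    DA/IA deletion counts, plus a per-deletion class listing in
    ``deletion_classes``.
    """
    act = activity.set_index("design_id")
    wt = designs[designs["role"] == "WT_FRAGMENT"].copy()
    wt["fragment"] = wt["design_id"].str.replace("_WT$", "", regex=True)
    offsets = designs.set_index("design_id")["deletion_offset"]
    rows = []
    for _, w in wt.iterrows():
        frag = w["fragment"]
        if w["design_id"] not in act.index or not bool(
                act.loc[w["design_id"], "passed_filter"]):
            continue  # no valid wild-type fragment
        dels = classed[classed["ref_id"] == w["design_id"]]
        classes = {int(offsets.get(a, -1)): c
                   for a, c in zip(dels["alt_id"], dels["class"])}
        rows.append({
            "fragment": frag,
            "wt_activity": float(act.loc[w["design_id"], "mean_activity"]),
            "n_da": int((dels["class"] == "MPRA-DA").sum()),
            "n_ia": int((dels["class"] == "MPRA-IA").sum()),
            "deletion_classes": classes,
        })
    return pd.DataFrame(rows)
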