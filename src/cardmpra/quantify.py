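"""Barcode counting, depth normalization (FPM), coverage filtering and
log2 RNA/DNA activity scores.

Activity of a design is ``log2((RNA_fpm + 1) / (DNA_fpm + 1))`` per
replicate, averaged across replicates; designs are kept only when covered
by >= 20 FPM in at least one DNA library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FPM_THRESHOLD = 20.0
PSEUDOCOUNT = 1.0


@dataclass
class BarcodeCountResult:
    counts: pd.DataFrame          # design_id, count
    n_assigned: int
    n_ambiguous: int
    n_unmatched: int


def _hamming_all(read_bc: str, barcodes: np.ndarray) -> np.ndarray:
    arr = np.frombuffer(read_bc.encode(), dtype=np.uint8)
    return (barcodes != arr).sum(axis=1)


def count_barcodes(reads: list[str] | pd.Series, manifest: pd.DataFrame,
                   max_mismatch: int = 1) -> BarcodeCountResult:
    """Assign reads to designs by barcode.

    A read's leading ``len(barcode)`` bases are compared against the
    manifest; it is assigned when exactly one barcode lies within
    ``max_mismatch``.  Ambiguous reads (two or more equally close barcodes
    within tolerance) are discarded and tallied.
    """
    bcs = manifest["barcode"].astype(str)
    if bcs.duplicated().any():
        dup = bcs[bcs.duplicated()].iloc[0]
        raise ValueError(f"duplicate barcode in manifest: {dup}")
    bc_len = len(bcs.iloc[0])
    exact = dict(zip(bcs, manifest["design_id"]))
    mat = np.array([np.frombuffer(b.encode(), dtype=np.uint8) for b in bcs])
    ids = manifest["design_id"].to_numpy()

    counts: dict[str, int] = {d: 0 for d in ids}
    n_assigned = n_ambiguous = n_unmatched = 0
    for read in reads:
        bc = str(read)[:bc_len]
        hit = exact.get(bc)
        if hit is not None:
            counts[hit] += 1
            n_assigned += 1
            continue
        if max_mismatch == 0:
            n_unmatched += 1
            continue
        d = _hamming_all(bc, mat)
        best = d.min()
        if best > max_mismatch:
            n_unmatched += 1
        elif (d == best).sum() > 1:
            n_ambiguous += 1
        else:
            counts[ids[int(d.argmin())]] += 1
            n_assigned += 1
    frame = pd.DataFrame({"design_id": list(counts), "count": list(counts.values())})
    return BarcodeCountResult(frame, n_assigned, n_ambiguous, n_unmatched)


def normalize_fpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Add an ``fpm`` column: count / (replicate-material library total) * 1e6.

    Totals are conserved: FPM sums to 1e6 within every library.
    """
    out = counts.copy()
    totals = out.groupby(["replicate", "material"])["count"].transform("sum")
    if (totals <= 0).any():
        bad = out.loc[totals <= 0, ["replicate", "material"]].iloc[0]
        raise ValueError(f"library {bad.tolist()} has zero total count")
    out["fpm"] = out["count"] / totals * 1e6
    return out


def filter_coverage(counts: pd.DataFrame,
                    threshold: float = FPM_THRESHOLD) -> pd.Series:
    """Keep a design iff its DNA FPM reaches ``threshold`` in >= 1 replicate.

    Returns a boolean Series indexed by design_id.
    """
    dna = counts[counts["material"] == "DNA"]
    if not len(dna):
        raise ValueError("no DNA records present")
    return dna.groupby("design_id")["fpm"].max() >= threshold


def activity_scores(counts: pd.DataFrame,
                    passed: pd.Series | None = None) -> pd.DataFrame:
    """Per-replicate and mean log2((RNA_fpm+1)/(DNA_fpm+1)) activity scores.

    Missing RNA records are treated as zero counts.  Returns a frame with
    design_id, replicate columns ``activity_rep{r}``, ``mean_activity`` and
    ``passed_filter``.
    """
    wide = counts.pivot_table(index="design_id", columns=["material", "replicate"],
                              values="fpm", aggfunc="first")
    reps = sorted({r for (_, r) in wide.columns})
    out = pd.DataFrame(index=wide.index)
    for r in reps:
        dna = wide.get(("DNA", r), pd.Series(0.0, index=wide.index)).fillna(0.0)
        rna = wide.get(("RNA", r), pd.Series(0.0, index=wide.index)).fillna(0.0)
        out[f"activity_rep{r}"] = np.log2((rna + PSEUDOCOUNT) / (dna + PSEUDOCOUNT))
    out["mean_activity"] = out.mean(axis=1)
    if passed is None:
        out["passed_filter"] = True
    else:
        out["passed_filter"] = passed.reindex(out.index).fillna(False).astype(bool)
    return out.reset_index()


def replicate_qc(activity: pd.DataFrame, floor: float = 0.8) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of per-replicate activities.

    Emits a warning column value below ``floor``; requires >= 2 replicates.
    """
    cols = [c for c in activity.columns if c.startswith("activity_rep")]
    if len(cols) < 2:
        raise ValueError("replicate QC needs at least two replicates")
    mat = activity[cols].corr(method="pearson")
    mat.index.name = mat.columns.name = "replicate"
    return mat
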