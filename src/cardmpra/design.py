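"""Oligo library designers for the three assay geometries.

* STARR layout: a 400 bp test region split over two self-priming 230 nt
  oligos with a 20 bp 3' overlap and 20 bp primer binding sites; the region
  in the reporter 3' UTR serves as its own barcode.
* Tiling mutagenesis: each 400 bp region represented as three overlapping
  171 bp fragments (F1/F2/F3), each tiled with 17 ten-bp deletions, every
  oligo uniquely barcoded.
* REF/ALT variant pairs: 171 bp of genomic sequence centered on a variant,
  one oligo per allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BARCODE_LENGTH = 15
PRIMER_LENGTH = 20
STARR_OLIGO_LENGTH = 230
STARR_REGION_LENGTH = 400
STARR_OVERLAP = 20
FRAGMENT_LENGTH = 171
DELETION_SIZE = 10
DELETIONS_PER_FRAGMENT = 17


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class OligoDesign:
    """One synthesized library member."""

    id: str
    role: str  # STARR_LEFT, STARR_RIGHT, WT_FRAGMENT, DELETION, REF, ALT, NEG_CONTROL, POS_CONTROL
    genomic_insert: str
    barcode: str | None = None
    left_primer: str = ""
    right_primer: str = ""
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    fragment_index: int | None = None
    deletion_offset: int | None = None
    variant_id: str | None = None
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.barcode is not None and len(self.barcode) != BARCODE_LENGTH:
            raise ValueError(f"barcode must be {BARCODE_LENGTH} nt")


@dataclass
class Variant:
    """A tested variant in VCF-like coordinates (pos is 1-based)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    participant_id: str = ""
    variant_id: str = ""

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        if not self.variant_id:
            self.variant_id = f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


def design_starr_pair(region: str, primer_left: str, primer_right: str,
                      region_id: str = "region") -> tuple[OligoDesign, OligoDesign]:
    """Split a 400 bp region over two 230 nt self-priming oligos.

    The left oligo is ``primer_left + region[0:210]``; the right oligo is
    synthesized on the opposite strand, ``primer_right + revcomp(region[190:400])``,
    so the two share a 20 bp 3' overlap (region positions 190-210) and
    self-priming extension reconstructs the full 400 bp region.
    """
    if len(region) != STARR_REGION_LENGTH:
        raise ValueError(
            f"{region_id}: STARR regions must be {STARR_REGION_LENGTH} bp, got {len(region)}")
    if len(primer_left) != PRIMER_LENGTH or len(primer_right) != PRIMER_LENGTH:
        raise ValueError("primers must be 20 nt")
    half = STARR_OLIGO_LENGTH - PRIMER_LENGTH  # 210
    left = OligoDesign(id=f"{region_id}_L", role="STARR_LEFT",
                       genomic_insert=region[:half],
                       left_primer=primer_left, right_primer=primer_right)
    right = OligoDesign(id=f"{region_id}_R", role="STARR_RIGHT",
                        genomic_insert=region[STARR_REGION_LENGTH - half:],
                        left_primer=primer_left, right_primer=primer_right)
    return left, right


def starr_oligo_sequences(left: OligoDesign, right: OligoDesign) -> tuple[str, str]:
    """Full 230 nt sequences as synthesized (5'->3', right on the minus strand)."""
    return (left.left_primer + left.genomic_insert,
            right.right_primer + revcomp(right.genomic_insert))


def assemble_starr(left: OligoDesign, right: OligoDesign) -> str:
    """In-silico self-priming assembly; round-trips design_starr_pair."""
    a, b = left.genomic_insert, right.genomic_insert
    if a[-STARR_OVERLAP:] != b[:STARR_OVERLAP]:
        raise ValueError("left/right oligos do not share the 20 bp overlap")
    return a + b[STARR_OVERLAP:]


class Barcoder:
    """Hands out unique barcodes from a pre-generated pool."""

    def __init__(self, pool: Iterable[str]):
        self._pool = list(pool)
        self._i = 0

    def next(self) -> str:
        if self._i >= len(self._pool):
            raise RuntimeError("barcode pool exhausted")
        bc = self._pool[self._i]
        self._i += 1
        return bc


def fragment_offsets(region_length: int = STARR_REGION_LENGTH) -> list[int]:
    """Start offsets of the three overlapping 171 bp fragments.

    F2 is centered on the region midpoint; F1 starts at 0 and F3 ends at the
    region end, giving adjacent overlaps of at least 55 bp on a 400 bp region.
    """
    return [0, (region_length - FRAGMENT_LENGTH) // 2, region_length - FRAGMENT_LENGTH]


def design_tiling(region: str, barcoder: Barcoder,
                  region_id: str = "region") -> list[OligoDesign]:
    """Tiling-deletion mutagenesis designs for one 400 bp region.

    Three 171 bp fragments, each emitted as a wild-type oligo plus 17
    deletion oligos lacking a 10 bp window at offsets 0, 10, ..., 160
    (insert length 161).  All 54 oligos get distinct barcodes.
    """
    if len(region) != STARR_REGION_LENGTH:
        raise ValueError(f"{region_id}: tiling regions must be {STARR_REGION_LENGTH} bp")
    designs: list[OligoDesign] = []
    for fi, off in enumerate(fragment_offsets(len(region)), start=1):
        frag = region[off:off + FRAGMENT_LENGTH]
        designs.append(OligoDesign(
            id=f"{region_id}_F{fi}_WT", role="WT_FRAGMENT", genomic_insert=frag,
            barcode=barcoder.next(), fragment_index=fi, start=off,
            end=off + FRAGMENT_LENGTH))
        for d in range(DELETIONS_PER_FRAGMENT):
            doff = d * DELETION_SIZE
            insert = frag[:doff] + frag[doff + DELETION_SIZE:]
            designs.append(OligoDesign(
                id=f"{region_id}_F{fi}_del{doff:03d}", role="DELETION",
                genomic_insert=insert, barcode=barcoder.next(),
                fragment_index=fi, deletion_offset=doff, start=off,
                end=off + FRAGMENT_LENGTH, pair_id=f"{region_id}_F{fi}"))
    return designs


def design_ref_alt(variant: Variant, genome: dict[str, str],
                   barcoder: Barcoder) -> tuple[OligoDesign, OligoDesign]:
    """REF/ALT oligo pair: 171 bp of genomic sequence centered on the variant.

    The first base of the REF allele sits at insert offset 85 (1-based 86).
    For indels the ALT insert keeps the same flanks, so its length is
    171 + (len(alt) - len(ref)).
    """
    chrom = genome.get(variant.chrom)
    if chrom is None:
        raise KeyError(f"chromosome {variant.chrom} not in genome")
    center = variant.pos - 1  # 0-based position of the ref allele's first base
    flank = (FRAGMENT_LENGTH - 1) // 2  # 85
    start = center - flank
    end = start + FRAGMENT_LENGTH
    if start < 0 or end > len(chrom):
        raise ValueError(f"{variant.variant_id}: 171 bp window exceeds chromosome bounds")
    ref_insert = chrom[start:end]
    observed = chrom[center:center + len(variant.ref_allele)]
    if observed.upper() != variant.ref_allele.upper():
        raise ValueError(
            f"{variant.variant_id}: reference allele mismatch at {variant.chrom}:"
            f"{variant.pos} (genome has {observed!r})")
    alt_insert = (ref_insert[:flank] + variant.alt_allele
                  + ref_insert[flank + len(variant.ref_allele):])
    pid = f"pair_{variant.variant_id}"
    ref = OligoDesign(id=f"{variant.variant_id}_REF", role="REF",
                      genomic_insert=ref_insert, barcode=barcoder.next(),
                      chrom=variant.chrom, start=start, end=end,
                      variant_id=variant.variant_id, pair_id=pid)
    alt = OligoDesign(id=f"{variant.variant_id}_ALT", role="ALT",
                      genomic_insert=alt_insert, barcode=barcoder.next(),
                      chrom=variant.chrom, start=start, end=end,
                      variant_id=variant.variant_id, pair_id=pid)
    return ref, alt


def _has_homopolymer(codes: np.ndarray, run: int) -> np.ndarray:
    """Boolean mask of rows containing a homopolymer longer than ``run``."""
    n, L = codes.shape
    bad = np.zeros(n, dtype=bool)
    streak = np.ones(n, dtype=int)
    for j in range(1, L):
        same = codes[:, j] == codes[:, j - 1]
        streak = np.where(same, streak + 1, 1)
        bad |= streak > run
    return bad


def assign_barcodes(n: int, length: int = BARCODE_LENGTH, min_hamming: int = 3,
                    seed: int = 0, max_homopolymer: int = 4,
                    batch: int = 4096) -> list[str]:
    """Random barcode set with pairwise Hamming distance >= ``min_hamming``
    and no homopolymer run longer than ``max_homopolymer``.

    Greedy rejection sampling over candidate batches; deterministic for a
    fixed seed.  Raises if the request is infeasible.
    """
    if n > 4 ** length:
        raise ValueError(f"cannot draw {n} distinct barcodes of length {length}")
    rng = np.random.default_rng(seed)
    kept = np.empty((0, length), dtype=np.int8)
    attempts = 0
    while kept.shape[0] < n:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("barcode sampling failed to converge; relax constraints")
        cand = rng.integers(0, 4, size=(batch, length), dtype=np.int8)
        cand = cand[~_has_homopolymer(cand, max_homopolymer)]
        for row in cand:
            if kept.shape[0] >= n:
                break
            if kept.shape[0]:
                dist = (kept != row).sum(axis=1)
                if dist.min() < min_hamming:
                    continue
            kept = np.vstack([kept, row])
    return ["".join("ACGT"[b] for b in row) for row in kept]


def prioritize_variants(variants: pd.DataFrame, gene_table: pd.DataFrame,
                        enhancers: pd.DataFrame | None = None,
                        tss_window: int = 20_000,
                        min_enhancer_gene_ncdnvs: int = 3) -> pd.DataFrame:
    """Select noncoding variants worth assaying.

    A variant is retained if it is noncoding and at least one of:
    (1) it lies in a supplied enhancer interval whose closest gene has at
    least ``min_enhancer_gene_ncdnvs`` cohort ncDNVs, (2) it lies within
    ``tss_window`` bp of the TSS of a prioritized gene, or (3) it carries an
    external ``priority_flag``.  Closest gene is by linear distance to the
    TSS with ties broken toward the lower TSS coordinate.

    ``gene_table`` needs columns ``gene``, ``chrom``, ``tss``, ``prioritized``;
    ``variants`` needs ``chrom``, ``pos`` and optionally ``coding`` and
    ``priority_flag`` boolean columns.
    """
    if "tss" not in gene_table.columns:
        raise KeyError("gene table must carry a 'tss' column")
    out = variants.copy()
    coding = out["coding"].to_numpy(bool) if "coding" in out.columns else np.zeros(len(out), bool)
    external = (out["priority_flag"].to_numpy(bool)
                if "priority_flag" in out.columns else np.zeros(len(out), bool))

    # ncDNV tally per closest gene (needed for the enhancer rule)
    gene_counts: dict[str, int] = {}
    closest = []
    for _, v in out.iterrows():
        g = _closest_gene(v["chrom"], v["pos"], gene_table)
        closest.append(g)
        if g is not None:
            gene_counts[g] = gene_counts.get(g, 0) + 1
    out["closest_gene"] = closest

    near_tss = np.zeros(len(out), bool)
    in_enh = np.zeros(len(out), bool)
    pri = gene_table[gene_table["prioritized"].astype(bool)]
    for i, (_, v) in enumerate(out.iterrows()):
        same = pri[pri["chrom"] == v["chrom"]]
        if len(same):
            d = (same["tss"] - v["pos"]).abs()
            near_tss[i] = bool((d <= tss_window).any())
        if enhancers is not None:
            hit = enhancers[(enhancers["chrom"] == v["chrom"])
                            & (enhancers["start"] < v["pos"])
                            & (v["pos"] <= enhancers["end"])]
            for _, e in hit.iterrows():
                g = _closest_gene(e["chrom"], (e["start"] + e["end"]) // 2, gene_table)
                if g is not None and gene_counts.get(g, 0) >= min_enhancer_gene_ncdnvs:
                    in_enh[i] = True
                    break
    out["near_prioritized_tss"] = near_tss
    out["in_recurrent_enhancer"] = in_enh
    out["retained"] = ~coding & (near_tss | in_enh | external)
    return out


def _closest_gene(chrom: str, pos: int, gene_table: pd.DataFrame) -> str | None:
    same = gene_table[gene_table["chrom"] == chrom]
    if not len(same):
        return None
    d = (same["tss"] - pos).abs()
    best = d.min()
    tied = same[d == best].sort_values("tss")
    return str(tied.iloc[0]["gene"])


def manifest_frame(designs: Iterable[OligoDesign]) -> pd.DataFrame:
    """Flatten designs to the TSV manifest layout."""
    return pd.DataFrame([{
        "design_id": d.id, "role": d.role, "barcode": d.barcode or "",
        "insert": d.genomic_insert, "chrom": d.chrom or "",
        "start": d.start if d.start is not None else -1,
        "end": d.end if d.end is not None else -1,
        "pair_id": d.pair_id or "", "variant_id": d.variant_id or "",
        "fragment_index": d.fragment_index if d.fragment_index is not None else -1,
        "deletion_offset": d.deletion_offset if d.deletion_offset is not None else -1,
    } for d in designs])
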