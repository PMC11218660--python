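"""PWM scanning with exact match p-values, variant-driven motif gain/loss
calls and the signed motif odds-ratio statistic.

Motif scores are reported on the -log10(p) scale, where p is the exact
tail probability of the best log-odds match under the background base
model.  A variant changes a motif when the score moves by at least 2
(a >= 100-fold change in match p-value) and the motif matched at
p < 1e-3 in at least one of the two alleles; losses (LoM) and gains (GoM)
are assigned from the sign of the score change.

The p-value machinery discretizes per-position log-odds scores to a fixed
granularity and background probabilities to integer weights, then builds
the score distribution by dynamic programming in exact integer arithmetic.
This makes the tail probabilities identical to what exhaustive enumeration
over all k-mers would give at the same discretization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
SCORE_GRANULARITY = 1e-3      # log2-odds units per integer score step
BACKGROUND_QUANTUM = 1 << 20  # background probs become integer weights /2^20
PSEUDOCOUNT = 1e-3            # added to matrix cells before log-odds
DELTA_THRESHOLD = 2.0         # |score change| for a LoM/GoM call
MATCH_P_CUTOFF = 1e-3         # motif must match this well in >= 1 allele

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def p_from_score(score: float) -> float:
    """Match p-value implied by a motif score on the -log10 scale."""
    return 10.0 ** (-score)


def score_from_p(p: float) -> float:
    return -np.log10(p)


@dataclass
class PWM:
    """Position weight matrix over A/C/G/T with a background model."""

    motif_id: str
    matrix: np.ndarray                 # length x 4 probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    family_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.background = np.asarray(self.background, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be length x 4")
        if len(self.matrix) < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("matrix rows must sum to 1")
        self._tables: dict = {}

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def int_scores(self) -> np.ndarray:
        """Per-position integer log2-odds scores at the chosen granularity."""
        probs = self.matrix + PSEUDOCOUNT
        probs = probs / probs.sum(axis=1, keepdims=True)
        lo = np.log2(probs / self.background)
        return np.round(lo / SCORE_GRANULARITY).astype(np.int64)

    def _score_table(self):
        """Exact integer-weight score distribution under the background.

        Returns (scores_desc, tail_weights, total_weight): for each
        achievable integer score s (descending), the summed integer weight
        of k-mers scoring >= s.  All arithmetic on weights is exact.
        """
        if "table" in self._tables:
            return self._tables["table"]
        q = np.round(self.background * BACKGROUND_QUANTUM).astype(np.int64)
        q = np.maximum(q, 1)
        s = self.int_scores()
        dist: dict[int, int] = {0: 1}
        for i in range(len(s)):
            nxt: dict[int, int] = {}
            for sc, w in dist.items():
                for b in range(4):
                    k = sc + int(s[i, b])
                    nxt[k] = nxt.get(k, 0) + w * int(q[b])
            dist = nxt
        scores = np.array(sorted(dist, reverse=True), dtype=np.int64)
        weights = [dist[int(x)] for x in scores]
        tails, acc = [], 0
        for w in weights:
            acc += w
            tails.append(acc)
        total = int(sum(int(v) for v in dist.values()))
        self._tables["table"] = (scores, tails, total)
        return self._tables["table"]

    def match_p(self, int_score: int) -> float:
        """Exact P(background k-mer score >= int_score)."""
        scores, tails, total = self._score_table()
        # scores are descending; find rightmost with score >= int_score
        idx = np.searchsorted(-scores, -int_score, side="right") - 1
        if idx < 0:
            # above the maximum achievable score
            return 0.0
        return tails[int(idx)] / total  # exact ints: correctly rounded division


@dataclass
class MotifHit:
    position: int          # 0-based offset of the match on the + strand
    strand: str            # '+' or '-'
    int_score: int
    log_odds: float        # log2-odds at the granularity used
    p: float


_CODE = {c: i for i, c in enumerate(ALPHABET)}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, -1) for c in seq.upper()], dtype=np.int64)


def scan_pwm(sequence: str, pwm: PWM,
             window: tuple[int, int] | None = None) -> MotifHit | None:
    """Best motif match on either strand whose span overlaps ``window``.

    ``window`` is a 0-based half-open interval on the sequence; ``None``
    scans the whole sequence.  Returns ``None`` when the sequence is shorter
    than the motif or no placement overlaps the window.
    """
    L = len(pwm)
    n = len(sequence)
    if n < L:
        return None
    lo, hi = (0, n) if window is None else window
    s = pwm.int_scores()
    fwd = _encode(sequence)
    rev = _encode(sequence.translate(_COMP)[::-1])
    best: MotifHit | None = None
    for off in range(0, n - L + 1):
        if off + L <= lo or off >= hi:
            continue
        for strand, codes in (("+", fwd), ("-", rev)):
            o = off if strand == "+" else n - L - off
            window_codes = codes[o:o + L]
            if (window_codes < 0).any():
                continue
            sc = int(s[np.arange(L), window_codes].sum())
            if best is None or sc > best.int_score:
                best = MotifHit(position=off, strand=strand, int_score=sc,
                                log_odds=sc * SCORE_GRANULARITY, p=np.nan)
    if best is not None:
        best.p = pwm.match_p(best.int_score)
    return best


def motif_score(hit: MotifHit | None) -> float:
    """-log10 match p-value of a hit; 0 when there is no hit."""
    if hit is None or not np.isfinite(hit.p) or hit.p <= 0:
        return 0.0 if hit is None else 320.0
    return float(-np.log10(hit.p))


def classify_changes(pairs: pd.DataFrame, pwms: list[PWM], window: int = 8,
                     delta_threshold: float = DELTA_THRESHOLD,
                     p_cutoff: float = MATCH_P_CUTOFF) -> pd.DataFrame:
    """Motif gain/loss calls for every pair x motif.

    ``pairs`` needs pair_id, ref_seq, alt_seq, ref_center, alt_center and a
    ``class`` column (MPRA-IA / MPRA-DA / MPRA-NS).  Matches are searched
    within ``window`` bp of the variant center on each allele (+-8 bp for
    variant libraries, +-10 bp for deletion libraries).  A motif is kept for
    a pair only when it matches with p < ``p_cutoff`` in at least one
    allele; the call is LoM when delta <= -threshold and GoM when
    delta >= +threshold, with delta = score_alt - score_ref.
    """
    score_gate = score_from_p(p_cutoff)
    rows = []
    for _, pr in pairs.iterrows():
        for pwm in pwms:
            w_ref = (max(0, int(pr["ref_center"]) - window),
                     min(len(pr["ref_seq"]), int(pr["ref_center"]) + window + 1))
            w_alt = (max(0, int(pr["alt_center"]) - window),
                     min(len(pr["alt_seq"]), int(pr["alt_center"]) + window + 1))
            s_ref = motif_score(scan_pwm(pr["ref_seq"], pwm, w_ref))
            s_alt = motif_score(scan_pwm(pr["alt_seq"], pwm, w_alt))
            if max(s_ref, s_alt) <= score_gate:
                continue
            delta = s_alt - s_ref
            if delta <= -delta_threshold:
                call = "LoM"
            elif delta >= delta_threshold:
                call = "GoM"
            else:
                call = "none"
            cls = pr.get("class", "MPRA-NS")
            if cls in ("MPRA-IA", "MPRA-DA") and call != "none":
                category = f"{cls}_{call}"
            else:
                category = "control" if cls == "MPRA-NS" else "none"
            rows.append((pr["pair_id"], pwm.motif_id, s_ref, s_alt, delta,
                         call, cls, category))
    return pd.DataFrame(rows, columns=["pair_id", "motif_id", "score_ref",
                                       "score_alt", "delta", "call",
                                       "activity_class", "category"])


def motif_odds_ratio(changes: pd.DataFrame, motif_id: str,
                     direction_class: str) -> dict:
    """Signed odds ratio linking motif changes to activity changes.

    P_mc is the proportion of ``direction_class`` (MPRA-IA or MPRA-DA)
    pairs whose motif score changed; P_mn the proportion among
    activity-unchanged (MPRA-NS) control pairs.  The unsigned OR is
    P_mc(1-P_mn) / (P_mn(1-P_mc)); the sign n is +1 when the motif behaves
    as an activator (score increased in MPRA-IA pairs or decreased in
    MPRA-DA pairs) and -1 otherwise.  Zero margin cells get Haldane 0.5
    smoothing, flagged in the output.
    """
    sub = changes[changes["motif_id"] == motif_id]
    eff = sub[sub["activity_class"] == direction_class]
    ctl = sub[sub["activity_class"] == "MPRA-NS"]
    if not len(eff) or not len(ctl):
        raise ValueError("need pairs in both the effect and control margins")
    a = int((eff["call"] != "none").sum())
    b = len(eff) - a
    c = int((ctl["call"] != "none").sum())
    d = len(ctl) - c
    smoothed = 0 in (a, b, c, d)
    if smoothed:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    p_mc = a / (a + b)
    p_mn = c / (c + d)
    mean_delta = eff.loc[eff["call"] != "none", "delta"].mean()
    if direction_class == "MPRA-IA":
        n_sign = 1 if (mean_delta if np.isfinite(mean_delta) else 0) > 0 else -1
    else:
        n_sign = 1 if (mean_delta if np.isfinite(mean_delta) else 0) < 0 else -1
    or_unsigned = (p_mc * (1 - p_mn)) / (p_mn * (1 - p_mc))
    return {"motif_id": motif_id, "direction_class": direction_class,
            "P_mc": p_mc, "P_mn": p_mn, "n_sign": n_sign,
            "or_value": n_sign * or_unsigned, "smoothed": smoothed}


def motif_frequency_ranking(changes: pd.DataFrame) -> pd.DataFrame:
    """Motifs ranked by how often they are perturbed by activity-changing
    mutations relative to activity-neutral ones.

    Motifs never perturbed in the effect classes are excluded.  Zero NS
    frequencies get 0.5-count smoothing so the ratio stays finite.
    """
    eff_pairs = changes[changes["activity_class"].isin(["MPRA-IA", "MPRA-DA"])]
    ns_pairs = changes[changes["activity_class"] == "MPRA-NS"]
    n_eff = eff_pairs["pair_id"].nunique()
    n_ns = ns_pairs["pair_id"].nunique()
    rows = []
    for motif_id, grp in changes.groupby("motif_id"):
        k_eff = grp[(grp["activity_class"] != "MPRA-NS")
                    & (grp["call"] != "none")]["pair_id"].nunique()
        if k_eff == 0:
            continue
        k_ns = grp[(grp["activity_class"] == "MPRA-NS")
                   & (grp["call"] != "none")]["pair_id"].nunique()
        f_eff = k_eff / max(n_eff, 1)
        f_ns = k_ns / max(n_ns, 1)
        ratio = f_eff / f_ns if f_ns > 0 else f_eff / ((0.5 / max(n_ns, 1)))
        rows.append((motif_id, k_eff, f_eff, k_ns, f_ns, ratio))
    out = pd.DataFrame(rows, columns=["motif_id", "n_effect", "freq_effect",
                                      "n_ns", "freq_ns", "ratio"])
    out = out.sort_values("ratio", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def read_meme(path) -> list[PWM]:
    """Read motifs from a minimal MEME-format file."""
    from Bio import motifs as bio_motifs
    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    bg = np.array([record.background[c] for c in ALPHABET], float)
    out = []
    for m in record:
        mat = np.column_stack([np.asarray(m.counts[c], float) for c in ALPHABET])
        mat = mat / mat.sum(axis=1, keepdims=True)
        out.append(PWM(motif_id=m.name, matrix=mat, background=bg))
    return out


def write_meme(pwms: list[PWM], path) -> None:
    """Write motifs in minimal MEME format."""
    bg = pwms[0].background if pwms else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{c} {p:.5f}" for c, p in zip(ALPHABET, bg)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            # large nsites keeps probability precision through parsers that
            # round to integer counts
            fh.write(f"letter-probability matrix: alength= 4 w= {len(p)} "
                     f"nsites= 1000000 E= 0\n")
            for row in p.matrix:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
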