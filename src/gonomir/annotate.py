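"""Sequential annotation cascade for unique small-RNA tags.

Each tag is assigned exactly one category, in fixed priority order:

1. known-RNA removal (mRNA, rRNA, tRNA, snRNA, snoRNA, repeat; exact match by
   default, first matching class wins);
2. conserved miRNA: a <=1-mismatch hit to a mature miRNA, split by whether the
   matching precursor maps to the genome (``conserved_miRNA_genome``) or the
   tag's own extended genomic context folds into a hairpin
   (``conserved_miRNA_hairpin``);
3. novel miRNA: no mature hit, but the tag maps to the genome and a flanked
   window folds into a valid hairpin;
4. piRNA homology: a <=1-mismatch hit to the piRNA set whose ungapped
   Karlin-Altschul E-value falls below 1e-4;
5. ``nohit`` otherwise.

The cascade is a partition: category counts always sum to the number of tags.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import brentq

from .simlib import ReferenceBundle, revcomp

REMOVAL_ORDER = ("mRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "repeat")

CATEGORIES = REMOVAL_ORDER + (
    "conserved_miRNA_genome", "conserved_miRNA_hairpin",
    "novel_miRNA", "piRNA_homolog", "nohit",
)


@dataclass(frozen=True)
class Hit:
    ref_id: str
    offset: int
    mismatches: int


class MismatchIndex:
    """Substring-alignment index over a named sequence set.

    Finds every ungapped alignment of a query inside any reference with at
    most ``max_mismatch`` substitutions, by vectorised sliding-window
    comparison over a zero-padded 2-D byte matrix.
    """

    def __init__(self, refs: dict[str, str]):
        self.ids = sorted(refs)
        self.lens = np.array([len(refs[i]) for i in self.ids])
        width = int(self.lens.max()) if self.ids else 0
        self.mat = np.zeros((len(self.ids), width), dtype=np.uint8)
        for r, rid in enumerate(self.ids):
            s = refs[rid].encode()
            self.mat[r, :len(s)] = np.frombuffer(s, dtype=np.uint8)

    def search(self, query: str, max_mismatch: int = 1) -> list[Hit]:
        L = len(query)
        if not self.ids or L > self.mat.shape[1]:
            return []
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        windows = sliding_window_view(self.mat, L, axis=1)
        mism = (windows != q).sum(axis=2)
        valid = np.arange(windows.shape[1])[None, :] + L <= self.lens[:, None]
        rows, cols = np.nonzero((mism <= max_mismatch) & valid)
        hits = [Hit(self.ids[r], int(c), int(mism[r, c])) for r, c in zip(rows, cols)]
        hits.sort(key=lambda h: (h.ref_id, h.offset))
        return hits

    def best(self, query: str, max_mismatch: int = 1) -> Hit | None:
        hits = self.search(query, max_mismatch)
        if not hits:
            return None
        return min(hits, key=lambda h: (h.mismatches, h.ref_id, h.offset))


def match_le1(query: str, refs: dict[str, str], max_mismatch: int = 1) -> list[Hit]:
    """One-shot substring search with <= ``max_mismatch`` substitutions."""
    if len(query) < 16:
        raise ValueError("query must be >= 16 nt")
    return MismatchIndex(refs).search(query, max_mismatch)


# ---------------------------------------------------------------------------
# hairpin folding

@dataclass
class HairpinResult:
    structure: str
    mfe: float  # kcal/mol for the RNAfold backend; -pairs for the built-in folder
    mature_arm: str  # '5p', '3p', or 'spanning'
    paired_bases_in_duplex: int
    passes: bool


def nussinov_pairs(seq: str, min_loop: int = 3) -> list[tuple[int, int]]:
    """Maximum base-pairing structure by Nussinov dynamic programming.

    Watson-Crick plus G:U wobble pairs; hairpin loops of at least
    ``min_loop`` unpaired bases. Ties are broken toward pairing the outermost
    ends first (deterministic traceback).
    """
    n = len(seq)
    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
    pairable = np.zeros((n, n), dtype=bool)
    ok = {(65, 84), (84, 65), (67, 71), (71, 67), (71, 84), (84, 71)}
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if (int(enc[i]), int(enc[j])) in ok:
                pairable[i, j] = True
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        i = np.arange(0, n - span)
        j = i + span
        best = M[i, j - 1].copy()
        pair_score = np.where(pairable[i, j], M[i + 1, j - 1] + 1, -1)
        np.maximum(best, pair_score, out=best)
        # bifurcation: max over k of M[i,k] + M[k+1,j]
        for ii, jj in zip(i, j):
            ks = np.arange(ii, jj)
            split = M[ii, ks] + M[ks + 1, jj]
            m = split.max()
            if m > best[jj - span]:
                best[jj - span] = m
        M[i, j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or M[i, j] == 0:
            continue
        if M[i, j] == M[i, j - 1]:
            stack.append((i, j - 1))
        elif pairable[i, j] and M[i, j] == M[i + 1, j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        else:
            for k in range(i, j):
                if M[i, j] == M[i, k] + M[k + 1, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return sorted(pairs)


def _dot_bracket(n: int, pairs: list[tuple[int, int]]) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i], s[j] = "(", ")"
    return "".join(s)


def _rnafold(seq: str) -> tuple[str, float] | None:
    exe = shutil.which("RNAfold")
    if exe is None:
        return None
    out = subprocess.run([exe, "--noPS"], input=seq + "\n", text=True,
                         capture_output=True, check=True).stdout.splitlines()
    struct, _, energy = out[1].partition(" ")
    return struct, float(energy.strip().strip("()"))


def _top_level_components(structure: str) -> int:
    depth = comps = 0
    for c in structure:
        if c == "(":
            if depth == 0:
                comps += 1
            depth += 1
        elif c == ")":
            depth -= 1
    return comps


def _predominant_stem(structure: str, pairs: list[tuple[int, int]],
                      start: int, end: int, min_fraction: float = 0.7) -> bool:
    """True when one top-level helix component holds >= ``min_fraction`` of
    all base pairs and contains the mature span's pairing partners.

    This is the single-predominant-stem-loop criterion: minor marginal
    helices in the flanks are tolerated, a structure split into rival
    top-level stems is not.
    """
    if not pairs:
        return False
    # top-level components as index ranges [a, b]
    comps, depth, a = [], 0, None
    for i, c in enumerate(structure):
        if c == "(":
            if depth == 0:
                a = i
            depth += 1
        elif c == ")":
            depth -= 1
            if depth == 0:
                comps.append((a, i))
    sizes = [sum(1 for i, j in pairs if lo <= i and j <= hi) for lo, hi in comps]
    main = int(np.argmax(sizes))
    lo, hi = comps[main]
    mature_pairs = [p for p in pairs
                    if (start <= p[0] < end) or (start <= p[1] < end)]
    if not mature_pairs:
        return False
    in_main = all(lo <= i and j <= hi for i, j in mature_pairs)
    return in_main and sizes[main] >= min_fraction * len(pairs)


def fold_hairpin(
    sequence: str,
    mature: str,
    backend: str = "nussinov",
    min_loop: int = 3,
    min_duplex_pairs: int = 14,
    min_paired_fraction: float = 0.55,
    mfe_threshold: float = -18.0,
) -> HairpinResult:
    """Fold a candidate precursor and test the miRNA-hairpin criteria.

    Passes iff (a) the structure is a single stem-loop (one helix component at
    the top level), (b) the mature sequence lies entirely in the 5' or 3' arm,
    (c) at least ``min_duplex_pairs`` of its bases are paired with the
    opposite arm, and (d) the fold score beats the backend threshold:
    MFE <= ``mfe_threshold`` kcal/mol for the thermodynamic ``rnafold``
    backend, paired fraction >= ``min_paired_fraction`` for the built-in
    maximum-pairing folder.
    """
    start = sequence.find(mature)
    if start < 0:
        raise ValueError("mature must be a substring of sequence")
    end = start + len(mature)
    n = len(sequence)

    if backend == "rnafold":
        res = _rnafold(sequence)
        if res is None:
            raise RuntimeError("RNAfold executable not found")
        structure, mfe = res
        pairs, stk = [], []
        for i, c in enumerate(structure):
            if c == "(":
                stk.append(i)
            elif c == ")":
                pairs.append((stk.pop(), i))
        pairs.sort()
        score_ok = mfe <= mfe_threshold
    elif backend == "nussinov":
        pairs = nussinov_pairs(sequence, min_loop)
        structure = _dot_bracket(n, pairs)
        mfe = -float(len(pairs))
        score_ok = (2 * len(pairs) / n) >= min_paired_fraction
    else:
        raise ValueError(f"unknown folding backend {backend!r}")

    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    mature_partners = [partner[i] for i in range(start, end) if i in partner]
    duplex = len(mature_partners)
    if not mature_partners:
        arm = "spanning"
    elif all(p >= end for p in mature_partners):
        arm = "5p"
    elif all(p < start for p in mature_partners):
        arm = "3p"
    else:
        arm = "spanning"

    passes = (
        _predominant_stem(structure, pairs, start, end)
        and arm in ("5p", "3p")
        and duplex >= min_duplex_pairs
        and score_ok
    )
    return HairpinResult(structure=structure, mfe=mfe, mature_arm=arm,
                         paired_bases_in_duplex=duplex, passes=passes)


# ---------------------------------------------------------------------------
# piRNA homology with ungapped Karlin-Altschul statistics

@lru_cache(maxsize=None)
def karlin_lambda(match: float = 1.0, mismatch: float = -2.0) -> float:
    """Karlin-Altschul lambda for an ungapped match/mismatch scheme on
    uniform base composition: the positive root of
    sum_ij p_i p_j exp(lambda * s_ij) = 1."""
    def f(lam):
        return 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0
    return brentq(f, 1e-9, 10.0)


def evalue(score: float, m: int, n: int, match: float = 1.0,
           mismatch: float = -2.0, K: float = 0.3) -> float:
    """Ungapped E-value E = K * m * n * exp(-lambda * S)."""
    lam = karlin_lambda(match, mismatch)
    return K * m * n * float(np.exp(-lam * score))


def pirna_homology(
    tag: str,
    pirna_index: MismatchIndex,
    max_mismatch: int = 1,
    evalue_max: float = 1e-4,
    match: float = 1.0,
    mismatch: float = -2.0,
    K: float = 0.3,
) -> tuple[Hit, float] | None:
    """Best <=1-mismatch piRNA hit passing the E-value criterion, or None.

    The alignment score is matches*s_match + mismatches*s_mismatch over the
    full tag; the database size n is the summed piRNA length.
    """
    best = pirna_index.best(tag, max_mismatch)
    if best is None:
        return None
    m = len(tag)
    n_db = int(pirna_index.lens.sum())
    score = (m - best.mismatches) * match + best.mismatches * mismatch
    E = evalue(score, m, n_db, match, mismatch, K)
    if E < evalue_max:
        return best, E
    return None


# ---------------------------------------------------------------------------
# the cascade

@dataclass
class AnnotationRecord:
    sequence: str
    category: str
    best_hit: str = ""
    mismatches: int | None = None
    evalue: float | None = None
    hairpin: HairpinResult | None = None


class Annotator:
    """Holds the reference indexes and applies the cascade to tags.

    ``removal_max_mismatch`` controls the known-RNA removal steps (exact by
    default); mature-miRNA and piRNA matching always allow one substitution,
    the homology criterion used throughout.
    """

    def __init__(
        self,
        bundle: ReferenceBundle,
        flank: int = 70,
        removal_max_mismatch: int = 0,
        mirna_max_mismatch: int = 1,
        fold_backend: str = "nussinov",
        evalue_max: float = 1e-4,
    ):
        self.bundle = bundle
        self.flank = flank
        self.removal_max_mismatch = removal_max_mismatch
        self.mirna_max_mismatch = mirna_max_mismatch
        self.fold_backend = fold_backend
        self.evalue_max = evalue_max

        pools = {"mRNA": bundle.mrna_frags, "repeat": bundle.repeats}
        pools.update({cls: bundle.ncrna[cls] for cls in bundle.ncrna})
        self.removal_indexes = {cls: MismatchIndex(pools[cls])
                                for cls in REMOVAL_ORDER}
        self.mature_index = MismatchIndex(bundle.mature_mirnas)
        self.pirna_index = MismatchIndex(bundle.pirnas)
        # genome as forward + reverse-complement strands for exact mapping
        self.genome_fwd = bundle.genome
        self.genome_rev = {c: revcomp(s) for c, s in bundle.genome.items()}
        joined = "".join(bundle.genome.values())
        self.genome_mapped_precursors = {
            mid for mid, pre in bundle.precursors.items() if pre in joined
        }

    def genome_hits(self, query: str) -> list[tuple[str, int, str]]:
        """Exact genomic matches as (chrom, start, strand); forward-strand
        coordinates, 0-based."""
        out = []
        for chrom, seq in self.genome_fwd.items():
            i = seq.find(query)
            while i >= 0:
                out.append((chrom, i, "+"))
                i = seq.find(query, i + 1)
        for chrom, seq in self.genome_rev.items():
            i = seq.find(query)
            while i >= 0:
                out.append((chrom, len(seq) - i - len(query), "-"))
                i = seq.find(query, i + 1)
        out.sort()
        return out

    def _hairpin_windows(self, tag: str):
        """Yield candidate precursor windows around each genomic locus of the
        tag: 5'-flank + tag (mature in 3p arm) and tag + 3'-flank (mature in
        5p arm), in mapped-strand orientation."""
        for chrom, start, strand in self.genome_hits(tag):
            seq = self.genome_fwd[chrom]
            end = start + len(tag)
            up = seq[max(0, start - self.flank):end]
            down = seq[start:min(len(seq), end + self.flank)]
            if strand == "-":
                up, down = revcomp(down), revcomp(up)
            for window in (up, down):
                if len(window) >= 50:
                    yield window

    def _try_fold(self, tag: str) -> HairpinResult | None:
        for window in self._hairpin_windows(tag):
            hp = fold_hairpin(window, tag, backend=self.fold_backend)
            if hp.passes:
                return hp
        return None

    def classify(self, tag: str) -> AnnotationRecord:
        """Apply the cascade to a single tag sequence."""
        for cls in REMOVAL_ORDER:
            hit = self.removal_indexes[cls].best(tag, self.removal_max_mismatch)
            if hit is not None:
                return AnnotationRecord(tag, cls, hit.ref_id, hit.mismatches)

        mhit = self.mature_index.best(tag, self.mirna_max_mismatch)
        if mhit is not None:
            if mhit.ref_id in self.genome_mapped_precursors:
                return AnnotationRecord(tag, "conserved_miRNA_genome",
                                        mhit.ref_id, mhit.mismatches)
            hp = self._try_fold(tag)
            if hp is not None:
                return AnnotationRecord(tag, "conserved_miRNA_hairpin",
                                        mhit.ref_id, mhit.mismatches, hairpin=hp)
            # known-mature tag with no genomic or hairpin evidence is excluded
            # from the miRNA catalogue; it continues down the cascade
        else:
            hp = self._try_fold(tag)
            if hp is not None:
                return AnnotationRecord(tag, "novel_miRNA",
                                        f"novel:{tag[:8]}", 0, hairpin=hp)

        pir = pirna_homology(tag, self.pirna_index,
                             evalue_max=self.evalue_max)
        if pir is not None:
            hit, E = pir
            return AnnotationRecord(tag, "piRNA_homolog", hit.ref_id,
                                    hit.mismatches, evalue=E)
        return AnnotationRecord(tag, "nohit")

    def annotate_tags(self, tag_table: pd.DataFrame) -> pd.DataFrame:
        """Annotate every row of a unique-tag table.

        Returns the tag table with ``category``, ``best_hit``, ``mismatches``
        and ``evalue`` columns appended; the categories partition the rows.
        """
        recs = [self.classify(seq) for seq in tag_table.index]
        out = tag_table.copy()
        out["category"] = [r.category for r in recs]
        out["best_hit"] = [r.best_hit for r in recs]
        out["mismatches"] = [r.mismatches if r.mismatches is not None else -1
                             for r in recs]
        out["evalue"] = [r.evalue if r.evalue is not None else np.nan
                         for r in recs]
        return out


def category_summary(annotated: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Per-category distinct-tag and per-library read-count totals."""
    count_cols = [c for c in annotated.columns if c.startswith("count_")]
    out = {}
    for cat in CATEGORIES:
        sub = annotated[annotated["category"] == cat]
        entry = {"distinct": int(len(sub))}
        for c in count_cols:
            entry[c] = int(sub[c].sum())
        out[cat] = entry
    return out
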