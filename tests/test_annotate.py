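"""The annotation cascade: mismatch matching, hairpin folding, piRNA homology."""

import dataclasses
from functools import lru_cache

import numpy as np
import pytest

from gonomir import annotate, preprocess, simlib
from gonomir.annotate import (Annotator, MismatchIndex, evalue, fold_hairpin,
                              karlin_lambda, match_le1, nussinov_pairs,
                              pirna_homology)


def brute_force_hits(query, refs, max_mismatch):
    hits = []
    for rid, ref in refs.items():
        for off in range(len(ref) - len(query) + 1):
            mism = sum(a != b for a, b in zip(query, ref[off:off + len(query)]))
            if mism <= max_mismatch:
                hits.append((rid, off, mism))
    return sorted(hits)


class TestMismatchMatching:
    def test_exact_hit(self, bundle):
        mid = sorted(bundle.mature_mirnas)[0]
        hits = match_le1(bundle.mature_mirnas[mid], bundle.mature_mirnas)
        assert any(h.ref_id == mid and h.mismatches == 0 for h in hits)

    def test_two_substitutions_rejected(self, bundle):
        mid = sorted(bundle.mature_mirnas)[0]
        seq = list(bundle.mature_mirnas[mid])
        for pos in (2, 7):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        hits = match_le1("".join(seq), {mid: bundle.mature_mirnas[mid]})
        assert hits == []

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            match_le1("ACGT", {"r": "ACGTACGTACGTACGTACGT"})

    def test_equals_exhaustive_scan_on_random_instances(self):
        """1000 seeded random queries against a 10-sequence toy index."""
        rng = np.random.default_rng(123)
        refs = {f"r{i}": "".join(rng.choice(list("ACGT"), 60))
                for i in range(10)}
        # seed some near-matches so hits actually occur
        idx = MismatchIndex(refs)
        for trial in range(1000):
            if trial % 3 == 0:
                rid = f"r{rng.integers(10)}"
                off = int(rng.integers(0, 41))
                q = list(refs[rid][off:off + 20])
                if rng.random() < 0.7:
                    p = int(rng.integers(20))
                    q[p] = str(rng.choice(list("ACGT")))
                query = "".join(q)
            else:
                query = "".join(rng.choice(list("ACGT"), 20))
            mm = int(rng.integers(0, 2))
            got = [(h.ref_id, h.offset, h.mismatches)
                   for h in idx.search(query, mm)]
            assert got == brute_force_hits(query, refs, mm)


def oracle_max_pairs(seq, min_loop=3):
    """Independent memoized-recursion Nussinov: maximum pair count only."""
    ok = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}

    @lru_cache(maxsize=None)
    def best(i, j):
        if j - i <= min_loop:
            return 0
        out = max(best(i, j - 1), best(i + 1, j))
        if (seq[i], seq[j]) in ok:
            out = max(out, best(i + 1, j - 1) + 1)
        for k in range(i + 1, j):
            out = max(out, best(i, k) + best(k + 1, j))
        return out

    return best(0, len(seq) - 1)


class TestHairpinFolding:
    def test_engineered_stem_loop_passes_5p(self):
        rng = np.random.default_rng(1)
        mature = "".join(rng.choice(list("ACGT"), 22))
        arm = "GAC" + mature + "CTG"
        seq = arm + "TTCGAATC" + simlib.revcomp(arm)
        hp = fold_hairpin(seq, mature)
        assert hp.passes and hp.mature_arm == "5p"
        assert hp.paired_bases_in_duplex >= 14
        assert len(hp.structure) == len(seq)
        assert hp.structure.count("(") == hp.structure.count(")")

    def test_homopolymer_fails(self):
        hp = fold_hairpin("A" * 80, "A" * 22)
        assert not hp.passes and hp.paired_bases_in_duplex == 0

    def test_mature_not_substring_raises(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGT" * 20, "TTTTTTTTTTTTTTTTTTTTTT")

    def test_simlib_precursor_matches_nussinov_oracle(self, bundle):
        """Engineered precursors pass; pair count equals an independent
        recursion-based maximum-pairing oracle."""
        for mid in sorted(bundle.mature_mirnas)[:3]:
            pre, mat = bundle.precursors[mid], bundle.mature_mirnas[mid]
            hp = fold_hairpin(pre, mat)
            assert hp.passes and hp.paired_bases_in_duplex >= 14
            assert len(nussinov_pairs(pre)) == oracle_max_pairs(pre)

    def test_poly_a_tail_does_not_reduce_duplex(self, bundle):
        mid = sorted(bundle.mature_mirnas)[0]
        pre, mat = bundle.precursors[mid], bundle.mature_mirnas[mid]
        base = fold_hairpin(pre, mat).paired_bases_in_duplex
        for tail in (4, 8, 16):
            tailed = fold_hairpin(pre + "A" * tail, mat)
            assert tailed.paired_bases_in_duplex >= base

    def test_rnafold_backend_agrees_on_engineered_precursor(self, bundle):
        mid = sorted(bundle.mature_mirnas)[0]
        hp = fold_hairpin(bundle.precursors[mid], bundle.mature_mirnas[mid],
                          backend="rnafold")
        assert hp.passes and hp.mfe <= -18.0


class TestPirnaHomology:
    def test_lambda_solves_karlin_equation(self):
        lam = karlin_lambda(1.0, -2.0)
        # independent bisection on 0.25 e^(lam) + 0.75 e^(-2 lam) = 1
        lo, hi = 0.5, 2.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if 0.25 * np.exp(mid) + 0.75 * np.exp(-2 * mid) < 1:
                lo = mid
            else:
                hi = mid
        assert lam == pytest.approx(lo, abs=1e-9)
        assert lam == pytest.approx(1.33, abs=0.02)

    def test_identical_tag_accepted(self, bundle):
        idx = MismatchIndex(bundle.pirnas)
        pid = sorted(bundle.pirnas)[0]
        res = pirna_homology(bundle.pirnas[pid], idx)
        assert res is not None
        hit, E = res
        assert hit.ref_id == pid and E < 1e-8

    def test_two_mismatches_rejected_regardless_of_evalue(self, bundle):
        pid = sorted(bundle.pirnas)[0]
        seq = list(bundle.pirnas[pid])
        for pos in (3, 9):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        assert pirna_homology("".join(seq), MismatchIndex(bundle.pirnas)) is None

    def test_evalue_threshold_crossing_with_database_size(self):
        """A short exact hit is rejected once K*m*n*exp(-lambda*S) >= 1e-4."""
        lam = karlin_lambda()
        m, K = 16, 0.3
        S = 16.0
        n_crit = 1e-4 / (K * m * np.exp(-lam * S))
        tag = "ACGTACGTACGTACGT"
        filler = "GGCC" * 8
        small_n = int(n_crit * 0.5)
        big_n = int(n_crit * 2.0)

        def build(total):
            refs = {"p0": tag + filler[:14]}  # 30-nt reference containing the tag
            i, remaining = 1, total - 30
            while remaining > 0:
                refs[f"p{i:04d}"] = filler[:min(30, remaining)].ljust(
                    min(30, remaining), "G")
                remaining -= 30
                i += 1
            return refs

        assert evalue(S, m, small_n) < 1e-4 < evalue(S, m, big_n)
        res_small = pirna_homology(tag, MismatchIndex(build(small_n)))
        assert res_small is not None
        assert pirna_homology(tag, MismatchIndex(build(big_n))) is None


class TestCascade:
    def test_mature_tag_is_conserved_genome(self, bundle):
        ann = Annotator(bundle)
        mid = sorted(bundle.mature_mirnas)[0]
        rec = ann.classify(bundle.mature_mirnas[mid])
        assert rec.category == "conserved_miRNA_genome"
        assert rec.best_hit == mid and rec.mismatches == 0

    def test_rrna_fragment_removed_before_mirna_steps(self, bundle):
        ann = Annotator(bundle)
        rid = sorted(bundle.ncrna["rRNA"])[0]
        frag = bundle.ncrna["rRNA"][rid][10:34]
        rec = ann.classify(frag)
        assert rec.category == "rRNA" and rec.best_hit == rid

    def test_planted_genomic_stem_loop_is_novel(self, bundle):
        rng = np.random.default_rng(9)
        tag = "".join(rng.choice(list("ACGT"), 22))
        arm = "GCA" + tag + "TGC"
        hairpin = arm + "TTCGAATC" + simlib.revcomp(arm)
        g = bundle.genome["chr1"]
        # plant inside the widest inter-precursor gap so no precursor is hit
        spans = sorted((s, s + len(bundle.precursors[m]))
                       for m, (_, s) in bundle.precursor_loci.items())
        gaps = [(spans[i + 1][0] - spans[i][1], spans[i][1])
                for i in range(len(spans) - 1)]
        width, gap_start = max(gaps)
        assert width > len(hairpin) + 20
        pos = gap_start + 10
        newg = g[:pos] + hairpin + g[pos + len(hairpin):]
        b2 = dataclasses.replace(bundle, genome={"chr1": newg})
        rec = Annotator(b2).classify(tag)
        assert rec.category == "novel_miRNA"

    def test_mature_without_genomic_precursor_uses_hairpin_evidence(self, bundle):
        """Deleting a precursor from the genome while planting the mature in
        a foldable genomic stem-loop yields hairpin-evidence conserved calls."""
        mid = sorted(bundle.mature_mirnas)[0]
        mat = bundle.mature_mirnas[mid]
        chrom, start = bundle.precursor_loci[mid]
        pre = bundle.precursors[mid]
        g = bundle.genome[chrom]
        rng = np.random.default_rng(4)
        scrub = "".join(rng.choice(list("ACGT"), len(pre)))
        arm = "GAC" + mat + "CTG"
        planted = arm + "TTCGAATC" + simlib.revcomp(arm)
        newg = g[:start] + scrub + g[start + len(pre):]
        newg = planted + newg[len(planted):]
        b2 = dataclasses.replace(bundle, genome={chrom: newg})
        rec = Annotator(b2).classify(mat)
        assert rec.category == "conserved_miRNA_hairpin"
        assert rec.best_hit == mid and rec.hairpin.passes

    def test_cascade_partitions_all_tags(self, bundle, tag_table):
        table, _ = tag_table
        annotated = Annotator(bundle).annotate_tags(table)
        assert len(annotated) == len(table)
        assert annotated["category"].isin(annotate.CATEGORIES).all()
        # counts per category sum to the per-library totals
        for col in ("count_XX", "count_XY", "count_YY"):
            assert annotated.groupby("category")[col].sum().sum() == table[col].sum()

    def test_category_recovery_against_truth(self, bundle, profile, sim_trio,
                                             tag_table):
        """At zero error rate >=99% of kept reads get their true category."""
        records, manifests = sim_trio
        table, _ = tag_table
        annotated = Annotator(bundle).annotate_tags(table)
        predicted = annotated["category"].to_dict()
        truth_map = {
            "miRNA": {"conserved_miRNA_genome", "conserved_miRNA_hairpin"},
            "piRNA": {"piRNA_homolog"},
            "random": {"nohit"},
        }
        good = total = 0
        for g in simlib.GROUPS:
            labels = {rid: cat for rid, cat, _ in manifests[g].read_labels}
            for rid, seq, _q in records[g]:
                trimmed, _ = preprocess.trim_adapter(seq, profile.adapter)
                if trimmed not in predicted:
                    continue  # read dropped by filtering
                truth = labels[rid]
                want = truth_map.get(truth, {truth})
                total += 1
                good += predicted[trimmed] in want
        assert total > 0
        assert good / total >= 0.99
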