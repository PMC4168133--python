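"""Synthetic small-RNA library generator with ground-truth bookkeeping.

Builds a toy reference bundle (genome, mature miRNAs embedded in near-palindromic
stem-loop precursors, housekeeping ncRNA classes, mRNA fragments, repeats,
piRNAs) and simulates three pooled gonad libraries (XX ovary, XY testis,
YY super-male testis) as adapter-carrying FASTQ reads. Every read is labelled
in a truth manifest so downstream annotation, normalization and differential
calls can be scored against known ground truth.

The design mirrors the study layout it emulates: one pooled library per
genotype group (no biological replicates), a Dicer-product peak at 22-23 nt and
a piRNA peak at 26-31 nt, per-group miRNA fold changes and group-exclusive
miRNA species.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

GROUPS = ("XX", "XY", "YY")
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: categories a simulated read can originate from
CATEGORIES = (
    "miRNA", "piRNA", "rRNA", "tRNA", "snRNA", "snoRNA",
    "mRNA", "repeat", "random",
)

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")
_NCRNA_LEN = {"rRNA": 120, "tRNA": 76, "snRNA": 110, "snoRNA": 90}

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode("ascii")


class CapacityError(ValueError):
    """Raised when precursors cannot be placed on the genome without overlap."""


@dataclass
class ReferenceBundle:
    """Toy reference collections the annotation cascade matches against.

    Every precursor embeds its mature miRNA as an exact substring and occurs
    exactly once on the genome; all sequences are over {A,C,G,T}.
    """

    genome: dict[str, str]
    mature_mirnas: dict[str, str]
    precursors: dict[str, str]
    ncrna: dict[str, dict[str, str]]
    mrna_frags: dict[str, str]
    repeats: dict[str, str]
    pirnas: dict[str, str]
    precursor_loci: dict[str, tuple[str, int]] = field(default_factory=dict)

    def validate(self) -> None:
        for mid, mat in self.mature_mirnas.items():
            pre = self.precursors[mid]
            if mat not in pre:
                raise ValueError(f"mature {mid} not a substring of its precursor")
        joined = "".join(self.genome.values())
        for mid, pre in self.precursors.items():
            if joined.count(pre) != 1:
                raise ValueError(f"precursor {mid} does not occur exactly once in genome")

    def write_fasta(self, outdir: str | Path) -> dict[str, Path]:
        """Write each collection as an uncompressed FASTA file; returns paths."""
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        collections = {
            "genome": self.genome,
            "mature": self.mature_mirnas,
            "precursor": self.precursors,
            "mrna": self.mrna_frags,
            "repeat": self.repeats,
            "pirna": self.pirnas,
        }
        for cls in NCRNA_CLASSES:
            collections[cls] = self.ncrna[cls]
        paths = {}
        for name, seqs in collections.items():
            p = outdir / f"{name}.fa"
            recs = [SeqRecord(Seq(s), id=k, description="") for k, s in sorted(seqs.items())]
            seqio_write(recs, str(p), "fasta")
            paths[name] = p
        return paths


@dataclass
class SimulationProfile:
    """Mixture and noise settings for one three-group simulation.

    ``de_spec`` entries are ``(mirna_id, (group_hi, group_lo), log2fc)``: the
    miRNA's mixture weight is multiplied by ``2**log2fc`` in ``group_hi``
    relative to its baseline weight used everywhere else. ``exclusive_spec``
    maps a group to miRNA ids whose weight is zeroed in the other two groups.
    """

    depth: int = 100_000
    category_fractions: dict[str, float] = field(default_factory=lambda: {
        "miRNA": 0.35, "piRNA": 0.25, "rRNA": 0.08, "tRNA": 0.08,
        "snRNA": 0.04, "snoRNA": 0.04, "mRNA": 0.05, "repeat": 0.05,
        "random": 0.06,
    })
    mirna_base_abundance: dict[str, float] | None = None
    de_spec: list[tuple[str, tuple[str, str], float]] = field(default_factory=list)
    exclusive_spec: dict[str, set[str]] = field(default_factory=dict)
    adapter: str = DEFAULT_ADAPTER
    error_rate: float = 0.001
    junk_fraction: float = 0.02
    dispersion: float = 0.0
    read_len: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")
        if set(self.category_fractions) != set(CATEGORIES):
            raise ValueError("category_fractions must cover exactly the known categories")
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_fractions sum to {total}, expected 1")
        for g in self.exclusive_spec:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in exclusive_spec")
        for _, (hi, lo), _ in self.de_spec:
            if hi not in GROUPS or lo not in GROUPS:
                raise ValueError(f"unknown group in de_spec pair ({hi}, {lo})")


@dataclass
class TruthManifest:
    """Per-read source labels plus aggregated per-miRNA truth for one library."""

    group: str
    read_labels: list[tuple[str, str, str]]  # (read_id, category, source_id)
    mirna_counts: dict[str, int]
    category_totals: dict[str, int]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tcategory\tsource_id\n")
            for rid, cat, src in self.read_labels:
                fh.write(f"{rid}\t{cat}\t{src}\n")


def generate_reference(
    n_mirnas: int = 50,
    n_pirnas: int = 30,
    n_ncrna_per_class: int = 5,
    genome_len: int = 30_000,
    seed: int = 0,
    n_mrna: int = 5,
    n_repeats: int = 5,
    arm_pad: int = 3,
    loop_len: int = 8,
    arm_mismatches: int = 2,
) -> ReferenceBundle:
    """Build a deterministic toy reference bundle.

    Precursors are constructed as near-palindromic stem-loops: a 5' arm padded
    around the mature sequence, a loop of ``loop_len`` (>= 6) nt, and the
    reverse complement of the arm carrying at most ``arm_mismatches``
    substitutions -- so hairpin validation passes by construction. Each
    precursor is placed exactly once, without overlap, on a single toy
    chromosome of random background sequence.

    Raises :class:`CapacityError` when the precursors cannot be hosted on
    ``genome_len`` nt without overlap.
    """
    if min(n_mirnas, n_pirnas, n_ncrna_per_class) < 1:
        raise ValueError("all reference counts must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    mature, precursors = {}, {}
    seen: set[str] = set()
    for i in range(n_mirnas):
        mid = f"mir-{i + 1:03d}"
        while True:
            m = _random_seq(rng, int(rng.integers(22, 24)))
            if m not in seen:
                seen.add(m)
                break
        arm = _random_seq(rng, arm_pad) + m + _random_seq(rng, arm_pad)
        loop = _random_seq(rng, loop_len)
        arm3 = list(revcomp(arm))
        for pos in rng.choice(len(arm3), size=arm_mismatches, replace=False):
            old = arm3[pos]
            arm3[pos] = str(rng.choice([b for b in "ACGT" if b != old]))
        mature[mid] = m
        precursors[mid] = arm + loop + "".join(arm3)

    # place precursors on one toy chromosome, non-overlapping, >=10 nt apart
    min_gap = 10
    need = sum(len(p) + min_gap for p in precursors.values())
    if need > genome_len:
        raise CapacityError(
            f"genome_len={genome_len} cannot host {n_mirnas} precursors "
            f"({need} nt required)"
        )
    chrom = list(_random_seq(rng, genome_len))
    slack = genome_len - need
    gaps = rng.multinomial(slack, np.full(n_mirnas, 1 / n_mirnas))
    loci = {}
    pos = 0
    for k, (mid, pre) in enumerate(sorted(precursors.items())):
        pos += int(gaps[k])
        chrom[pos:pos + len(pre)] = list(pre)
        loci[mid] = ("chr1", pos)
        pos += len(pre) + min_gap
    genome = {"chr1": "".join(chrom)}

    ncrna = {
        cls: {
            f"{cls}-{i + 1}": _random_seq(rng, _NCRNA_LEN[cls])
            for i in range(n_ncrna_per_class)
        }
        for cls in NCRNA_CLASSES
    }
    mrna = {f"mrna-{i + 1}": _random_seq(rng, 200) for i in range(n_mrna)}
    repeats = {f"rep-{i + 1}": _random_seq(rng, 150) for i in range(n_repeats)}
    # piRNA lengths peak at 26-28 nt, mirroring the PIWI-bound size mode
    pir_lens = rng.choice(np.arange(26, 32), size=n_pirnas,
                          p=[0.30, 0.30, 0.25, 0.08, 0.05, 0.02])
    pirnas = {
        f"pir-{i + 1:03d}": _random_seq(rng, int(pir_lens[i]))
        for i in range(n_pirnas)
    }

    bundle = ReferenceBundle(
        genome=genome, mature_mirnas=mature, precursors=precursors,
        ncrna=ncrna, mrna_frags=mrna, repeats=repeats, pirnas=pirnas,
        precursor_loci=loci,
    )
    bundle.validate()
    return bundle


def _mirna_weights(bundle: ReferenceBundle, profile: SimulationProfile,
                   group: str) -> tuple[list[str], np.ndarray]:
    """Per-miRNA mixture weights for one group (Zipf baseline by id rank)."""
    ids = sorted(bundle.mature_mirnas)
    if profile.mirna_base_abundance is not None:
        missing = set(profile.mirna_base_abundance) - set(ids)
        if missing:
            raise KeyError(f"profile references unknown miRNA ids: {sorted(missing)}")
        w = np.array([profile.mirna_base_abundance.get(i, 0.0) for i in ids])
    else:
        w = 1.0 / np.arange(1, len(ids) + 1)
    w = w.astype(float).copy()
    for mid, (hi, _lo), lfc in profile.de_spec:
        if mid not in bundle.mature_mirnas:
            raise KeyError(f"de_spec references unknown miRNA id {mid!r}")
        if group == hi:
            w[ids.index(mid)] *= 2.0 ** lfc
    for g, members in profile.exclusive_spec.items():
        for mid in members:
            if mid not in bundle.mature_mirnas:
                raise KeyError(f"exclusive_spec references unknown miRNA id {mid!r}")
            if group != g:
                w[ids.index(mid)] = 0.0
    if w.sum() <= 0:
        raise ValueError("miRNA mixture weights sum to zero")
    return ids, w / w.sum()


def expected_mirna_counts(bundle: ReferenceBundle, profile: SimulationProfile,
                          group: str) -> dict[str, float]:
    """Exact expected per-miRNA read counts from the mixture weights."""
    ids, w = _mirna_weights(bundle, profile, group)
    n_junk = int(round(profile.junk_fraction * profile.depth))
    n_mirna = (profile.depth - n_junk) * profile.category_fractions["miRNA"]
    return {i: n_mirna * wi for i, wi in zip(ids, w)}


def simulate_library(
    bundle: ReferenceBundle, profile: SimulationProfile, group: str,
) -> tuple[list[tuple[str, str, str]], TruthManifest]:
    """Simulate one library; returns (FASTQ records, truth manifest).

    Records are ``(read_id, sequence, quality)`` triples at fixed machine
    length ``profile.read_len``: the insert, then the 3' adapter filling the
    remainder (truncated as needed). Substitution errors are applied uniformly
    at ``profile.error_rate``. Junk reads (random sequence, Phred 2 quality)
    make up ``profile.junk_fraction`` of the depth. A single RNG stream keyed
    on ``(profile.seed, group)`` makes output bit-identical across runs.
    """
    profile.validate()
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    gidx = GROUPS.index(group)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=profile.seed,
                                                       spawn_key=(gidx,)))
    L = profile.read_len
    hi_qual = "I" * L

    n_junk = int(round(profile.junk_fraction * profile.depth))
    n_real = profile.depth - n_junk
    cats = list(CATEGORIES)
    frac = np.array([profile.category_fractions[c] for c in cats])
    if profile.dispersion > 0:
        # gamma-perturbed mixture weights -> overdispersed category counts
        frac = frac * rng.gamma(1.0 / profile.dispersion, profile.dispersion, len(frac))
        frac = frac / frac.sum()
    cat_counts = rng.multinomial(n_real, frac)

    inserts: list[tuple[str, str, str]] = []  # (sequence, category, source_id)

    for cat, n in zip(cats, cat_counts):
        if n == 0:
            continue
        if cat == "miRNA":
            ids, w = _mirna_weights(bundle, profile, group)
            per = rng.multinomial(n, w)
            for mid, k in zip(ids, per):
                seq = bundle.mature_mirnas[mid]
                inserts.extend([(seq, cat, mid)] * int(k))
        elif cat == "piRNA":
            ids = sorted(bundle.pirnas)
            per = rng.multinomial(n, np.full(len(ids), 1 / len(ids)))
            for pid, k in zip(ids, per):
                inserts.extend([(bundle.pirnas[pid], cat, pid)] * int(k))
        elif cat == "random":
            for _ in range(n):
                inserts.append((_random_seq(rng, int(rng.integers(16, 29))), cat, "-"))
        else:
            if cat == "mRNA":
                pool = bundle.mrna_frags
            elif cat == "repeat":
                pool = bundle.repeats
            else:
                pool = bundle.ncrna[cat]
            ids = sorted(pool)
            picks = rng.integers(0, len(ids), size=n)
            lens = rng.integers(18, 31, size=n)
            for pi, fl in zip(picks, lens):
                ref = pool[ids[pi]]
                fl = min(int(fl), len(ref))
                start = int(rng.integers(0, len(ref) - fl + 1))
                inserts.append((ref[start:start + fl], cat, ids[pi]))

    order = rng.permutation(len(inserts))
    records: list[tuple[str, str, str]] = []
    labels: list[tuple[str, str, str]] = []
    seqs: list[str] = []
    for ridx, j in enumerate(order):
        ins, cat, src = inserts[j]
        read = (ins + profile.adapter * (L // len(profile.adapter) + 2))[:L]
        rid = f"{group}:{ridx + 1}"
        seqs.append(read)
        labels.append((rid, cat, src))
    # substitution errors, vectorised over the whole library
    if profile.error_rate > 0 and seqs:
        arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).copy()
        n_err = rng.binomial(arr.size, profile.error_rate)
        if n_err:
            pos = rng.choice(arr.size, size=n_err, replace=False)
            shift = rng.integers(1, 4, size=n_err)
            lut = {65: 0, 67: 1, 71: 2, 84: 3}
            idx = np.array([lut[b] for b in arr[pos]])
            arr[pos] = BASES[(idx + shift) % 4]
        flat = arr.tobytes().decode()
        seqs = [flat[i * L:(i + 1) * L] for i in range(len(seqs))]
    for (rid, _c, _s), read in zip(labels, seqs):
        records.append((rid, read, hi_qual))

    for j in range(n_junk):
        jl = int(rng.integers(12, L + 1))
        rid = f"{group}:junk{j + 1}"
        records.append((rid, _random_seq(rng, jl), "#" * jl))
        labels.append((rid, "junk", "-"))

    mirna_counts: dict[str, int] = {}
    category_totals: dict[str, int] = {}
    for _rid, cat, src in labels:
        category_totals[cat] = category_totals.get(cat, 0) + 1
        if cat == "miRNA":
            mirna_counts[src] = mirna_counts.get(src, 0) + 1
    manifest = TruthManifest(group=group, read_labels=labels,
                             mirna_counts=mirna_counts,
                             category_totals=category_totals)
    assert sum(category_totals.values()) == profile.depth
    return records, manifest


def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, seq, qual) records as Sanger/Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def simulate_all(bundle: ReferenceBundle, profile: SimulationProfile,
                 ) -> tuple[dict[str, list], dict[str, TruthManifest]]:
    """Simulate the three-group design; returns per-group records and manifests."""
    recs, mans = {}, {}
    for g in GROUPS:
        recs[g], mans[g] = simulate_library(bundle, profile, g)
    return recs, mans
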