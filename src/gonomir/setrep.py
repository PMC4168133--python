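"""Detection-set Venn accounting, expression clustering, and the pipeline
driver.

The three-library design induces a seven-region Venn partition of the detected
miRNA species. Besides computing the partition from realized detection sets,
:func:`solve_partition` reconstructs the full partition from the marginal
counts a report typically prints (per-library totals, exclusive counts, and
one pairwise-only region), solving the small linear system for the remaining
regions and refusing infeasible inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simlib import GROUPS

REGIONS = (
    ("XX",), ("XY",), ("YY",),
    ("XX", "XY"), ("XX", "YY"), ("XY", "YY"),
    ("XX", "XY", "YY"),
)


class InfeasiblePartitionError(ValueError):
    """Raised when marginal counts admit no non-negative integer partition."""


@dataclass
class VennPartition:
    """Region counts for the seven disjoint regions of three detection sets.

    Region keys are sorted tuples of group names; a length-1 key is that
    group's exclusive region, length-2 a pairwise-only region, and the
    length-3 key the triple overlap.
    """

    regions: dict[tuple[str, ...], int] = field(default_factory=dict)

    def __post_init__(self):
        for r in REGIONS:
            self.regions.setdefault(r, 0)
        if any(v < 0 for v in self.regions.values()):
            raise ValueError("region counts must be non-negative")

    def set_total(self, group: str) -> int:
        return sum(v for k, v in self.regions.items() if group in k)

    def pairwise(self, a: str, b: str) -> int:
        """Co-detection count of two groups: their pair-only region plus the
        triple overlap."""
        key = tuple(sorted((a, b)))
        return self.regions[key] + self.regions[tuple(sorted(GROUPS))]

    @property
    def union(self) -> int:
        return sum(self.regions.values())

    def percentage(self, key: tuple[str, ...]) -> float:
        """Region share of the union, as a percentage to one decimal."""
        return round(100.0 * self.regions[tuple(sorted(key))] / self.union, 1)

    def set_percentage(self, group: str) -> float:
        return round(100.0 * self.set_total(group) / self.union, 1)

    def as_dict(self) -> dict:
        return {
            "regions": {"&".join(k): v for k, v in sorted(self.regions.items())},
            "set_totals": {g: self.set_total(g) for g in GROUPS},
            "pairwise": {f"{a}&{b}": self.pairwise(a, b)
                         for a, b in (("XX", "XY"), ("XX", "YY"), ("XY", "YY"))},
            "union": self.union,
            "percentages": {"&".join(k): self.percentage(k) for k in REGIONS},
        }


def venn_partition(detected: dict[str, set]) -> VennPartition:
    """Exact seven-region partition of three detection sets.

    Detection means any nonzero expression (NE > 0) unless the caller has
    already applied a stricter membership rule.
    """
    groups = sorted(detected)
    if len(groups) != 3:
        raise ValueError("exactly three detection sets required")
    regions: dict[tuple[str, ...], int] = {}
    union = set().union(*detected.values())
    for item in union:
        key = tuple(sorted(g for g in groups if item in detected[g]))
        regions[key] = regions.get(key, 0) + 1
    return VennPartition(regions={r: regions.get(r, 0) for r in REGIONS})


def solve_partition(
    totals: dict[str, int],
    exclusives: dict[str, int],
    pair_only: tuple[tuple[str, str], int],
) -> VennPartition:
    """Reconstruct the seven-region partition from printed marginals.

    Given the three per-set totals, the three exclusive counts and one
    pairwise-only region, the three remaining regions (the two other
    pairwise-only regions and the triple overlap) satisfy a 3x3 linear
    system; it is solved exactly and validated for non-negative integer
    solutions, raising :class:`InfeasiblePartitionError` otherwise.
    """
    if set(totals) != set(GROUPS) or set(exclusives) != set(GROUPS):
        raise ValueError(f"totals and exclusives must cover {GROUPS}")
    (pa, pb), g = pair_only
    if g < 0 or any(v < 0 for v in totals.values()) or any(v < 0 for v in exclusives.values()):
        raise ValueError("inputs must be non-negative")
    pa, pb = sorted((pa, pb))
    (pc,) = set(GROUPS) - {pa, pb}

    # unknowns: u = pair-only(pa,pc), v = pair-only(pb,pc), t = triple
    # totals:   pa = excl_a + g + u + t ; pb = excl_b + g + v + t
    #           pc = excl_c + u + v + t
    A = np.array([[1.0, 0.0, 1.0],
                  [0.0, 1.0, 1.0],
                  [1.0, 1.0, 1.0]])
    rhs = np.array([
        totals[pa] - exclusives[pa] - g,
        totals[pb] - exclusives[pb] - g,
        totals[pc] - exclusives[pc],
    ], dtype=float)
    u, v, t = np.linalg.solve(A, rhs)
    regions = {
        (pa,): exclusives[pa], (pb,): exclusives[pb], (pc,): exclusives[pc],
        tuple(sorted((pa, pb))): g,
        tuple(sorted((pa, pc))): u,
        tuple(sorted((pb, pc))): v,
        tuple(sorted(GROUPS)): t,
    }
    clean: dict[tuple[str, ...], int] = {}
    for key, val in regions.items():
        iv = round(val)
        if abs(val - iv) > 1e-6:
            raise InfeasiblePartitionError(
                f"region {'&'.join(key)} solves to non-integer {val}")
        if iv < 0:
            raise InfeasiblePartitionError(
                f"region {'&'.join(key)} solves to negative count {iv}")
        clean[tuple(sorted(key))] = int(iv)
    return VennPartition(regions={r: clean[r] for r in REGIONS})


# ---------------------------------------------------------------------------
# clustering

def cluster_order(ne: pd.DataFrame, metric: str = "euclidean",
                  method: str = "complete", zero_value: float = 0.01,
                  ) -> tuple[list[str], np.ndarray]:
    """Hierarchical clustering of log10-transformed expression rows.

    Zeros are replaced by ``zero_value`` before the log10 transform (the
    scatter/heatmap convention). Rows are pre-sorted by id so the
    agglomeration -- complete linkage on Euclidean distances by default --
    and the returned leaf order are independent of input row order.
    Returns (leaf ids, scipy linkage matrix).
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    if len(ne) < 2:
        raise ValueError("clustering needs at least two rows")
    mat = ne.sort_index()
    vals = mat.to_numpy(dtype=float).copy()
    vals[vals == 0] = zero_value
    vals = np.log10(vals)
    Z = hierarchy.linkage(pdist(vals, metric=metric), method=method)
    leaves = hierarchy.leaves_list(Z)
    return [mat.index[i] for i in leaves], Z


# ---------------------------------------------------------------------------
# pipeline driver

def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute simulate -> preprocess -> annotate -> DE -> set report.

    ``config`` mirrors the CLI surface: a ``simulate`` block (reference and
    profile settings) or a ``fastq`` mapping of group to path, plus optional
    ``adapter``, ``de`` and ``venn`` settings. Writes all report tables under
    ``outdir`` and returns the in-memory objects keyed by stage.
    """
    from . import annotate as ann
    from . import destats, preprocess, simlib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict = {}

    stage = "simulate"
    try:
        if "simulate" in config:
            sim = dict(config["simulate"])
            ref_kw = sim.pop("reference", {})
            seed = sim.pop("seed", 0)
            bundle = simlib.generate_reference(seed=seed, **ref_kw)
            profile = simlib.SimulationProfile(seed=seed, **sim)
            records, manifests = simlib.simulate_all(bundle, profile)
            bundle.write_fasta(outdir / "reference")
            for g, recs in records.items():
                simlib.write_fastq(recs, outdir / f"{g}.fastq")
                manifests[g].write_tsv(outdir / f"manifest_{g}.tsv")
            adapter = profile.adapter
            out["bundle"], out["manifests"] = bundle, manifests
        elif "fastq" in config:
            stage = "preprocess"
            records = {g: list(preprocess.read_fastq(p))
                       for g, p in config["fastq"].items()}
            bundle = config["bundle"]
            adapter = config.get("adapter", simlib.DEFAULT_ADAPTER)
        else:
            raise ValueError("config needs a 'simulate' block or 'fastq' paths")

        stage = "preprocess"
        tag_table, stats = preprocess.preprocess_libraries(records, adapter)
        tag_table.to_csv(outdir / "tag_table.tsv", sep="\t")
        with open(outdir / "filter_stats.json", "w") as fh:
            json.dump({g: s.as_dict() for g, s in stats.items()}, fh, indent=1)
        out["tag_table"], out["filter_stats"] = tag_table, stats

        stage = "annotate"
        annotator = ann.Annotator(bundle, **config.get("annotate", {}))
        annotated = annotator.annotate_tags(tag_table)
        annotated.to_csv(outdir / "annotation.tsv", sep="\t")
        with open(outdir / "category_summary.json", "w") as fh:
            json.dump(ann.category_summary(annotated), fh, indent=1)
        out["annotated"] = annotated

        stage = "destats"
        de_cfg = config.get("de", {})
        em = destats.expression_from_annotation(
            annotated, norm_total=de_cfg.get("norm_total", "mirna"))
        em.counts.join(em.ne, lsuffix="_count", rsuffix="_ne").to_csv(
            outdir / "expression.tsv", sep="\t")
        out["expression"] = em
        pairs = de_cfg.get("pairs", [("XY", "XX"), ("YY", "XX"), ("XY", "YY")])
        de_tables = {}
        for a, b in pairs:
            de = destats.call_de(
                em, (a, b),
                alpha=de_cfg.get("alpha", 0.05), lfc=de_cfg.get("lfc", 1.0),
                test_policy=de_cfg.get("policy", "ac"))
            de.to_csv(outdir / f"de_{a}_vs_{b}.tsv", sep="\t")
            destats.plot_values(em, (a, b)).to_csv(
                outdir / f"scatter_{a}_vs_{b}.tsv", sep="\t")
            de_tables[(a, b)] = de
        out["de"] = de_tables

        stage = "setrep"
        detected = {g: set(em.ne.index[em.ne[g] > 0]) for g in em.libraries}
        venn = venn_partition(detected)
        with open(outdir / "venn.json", "w") as fh:
            json.dump(venn.as_dict(), fh, indent=1)
        out["venn"] = venn
        if len(em.ne) >= 2:
            leaves, Z = cluster_order(em.ne)
            with open(outdir / "cluster_order.json", "w") as fh:
                json.dump({"leaves": leaves, "linkage": Z.tolist()}, fh)
            out["cluster"] = leaves

        with open(outdir / "runlog.json", "w") as fh:
            json.dump({"config": {k: str(v) for k, v in config.items()},
                       "libraries": list(GROUPS)}, fh, indent=1)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
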