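"""Runs-of-homozygosity detection and shared-region intersection.

In a consanguineous pedigree, a recessive disease locus lies inside a
genomic segment that is autozygous (homozygous by descent) in every
affected individual. Detection works on an ordered biallelic genotype
matrix: per sample, maximal runs of consecutive homozygous markers are
reported, tolerating a small number of heterozygous and missing calls
(genotyping error); candidate regions are the genomic intervals contained
in an ROH of every affected sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

HOM_CALLS = {"AA", "BB"}
HET_CALL = "AB"
MISSING_CALL = "NC"
VALID_CALLS = HOM_CALLS | {HET_CALL, MISSING_CALL}


class GenotypeError(ValueError):
    pass


def region_size_mb(start: int, end: int) -> float:
    """Interval size in Mb, (end - start)/1e6 rounded half-up to 1 decimal.

    The end-start (not +1) convention reproduces the sizes quoted for
    regions given by their bounding marker positions.
    """
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    mb = Decimal(end - start) / Decimal(10**6)
    return float(mb.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RohRegion:
    """A maximal homozygous run (or an intersection of such runs)."""

    chrom: str
    start: int
    end: int
    n_markers: int = 0
    n_het_tolerated: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region end {self.end} < start {self.start}")

    @property
    def size_mb(self) -> float:
        return region_size_mb(self.start, self.end)


@dataclass
class RohParams:
    """Run-definition knobs.

    Defaults target multi-megabase autozygous segments on array-density
    data while tolerating occasional genotyping error: at least 25 markers
    and 1 Mb per run, at most 1 heterozygous and 2 missing calls inside it.
    """

    min_markers: int = 25
    min_length_bp: int = 1_000_000
    max_het: int = 1
    max_missing: int = 2

    def __post_init__(self) -> None:
        if self.min_markers < 1 or self.min_length_bp < 0:
            raise ValueError("min_markers must be >= 1 and min_length_bp >= 0")
        if self.max_het < 0 or self.max_missing < 0:
            raise ValueError("max_het and max_missing must be >= 0")


class GenotypeMatrix:
    """Ordered biallelic SNP calls: markers (chrom, pos, id) x samples.

    Calls are coded AA/AB/BB/NC; positions are strictly increasing within
    each chromosome.
    """

    def __init__(self, markers: pd.DataFrame, calls: pd.DataFrame):
        markers = markers.reset_index(drop=True)
        calls = calls.reset_index(drop=True)
        if list(markers.columns[:3]) != ["chrom", "pos", "id"]:
            raise GenotypeError("markers must have columns chrom, pos, id")
        if len(markers) != len(calls):
            raise GenotypeError("markers and calls row counts differ")
        for chrom, grp in markers.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise GenotypeError(
                    f"positions not strictly increasing on {chrom}"
                )
        bad = set(calls.values.ravel()) - VALID_CALLS
        if bad:
            raise GenotypeError(f"invalid genotype codes: {sorted(bad)!r}")
        self.markers = markers
        self.calls = calls

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    def __len__(self) -> int:
        return len(self.markers)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        markers = df[["chrom", "pos", "id"]]
        calls = df.drop(columns=["chrom", "pos", "id"])
        return cls(markers, calls)

    def to_tsv(self, path: str | Path) -> None:
        pd.concat([self.markers, self.calls], axis=1).to_csv(
            path, sep="\t", index=False
        )

    def count_markers_in(self, chrom: str, start: int, end: int) -> int:
        m = self.markers
        return int(
            ((m["chrom"] == chrom) & (m["pos"] >= start) & (m["pos"] <= end)).sum()
        )


def detect_roh(
    g: GenotypeMatrix, sample: str, params: RohParams | None = None
) -> list[RohRegion]:
    """Maximal runs of consecutive markers homozygous in one sample.

    A run is bounded by homozygous markers, contains at most ``max_het``
    heterozygous and ``max_missing`` missing calls, and cannot be extended
    in either direction without breaking those bounds. Runs with fewer than
    ``min_markers`` markers or spanning less than ``min_length_bp`` (end -
    start) are discarded.
    """
    params = params or RohParams()
    if sample not in g.calls.columns:
        raise GenotypeError(f"unknown sample {sample!r}")
    if len(g) == 0:
        raise GenotypeError("empty genotype matrix")

    regions: list[RohRegion] = []
    for chrom, idx in g.markers.groupby("chrom", sort=False).groups.items():
        calls = g.calls.loc[idx, sample].to_numpy()
        pos = g.markers.loc[idx, "pos"].to_numpy()
        regions.extend(_detect_roh_chrom(str(chrom), pos, calls, params))
    return regions


def _detect_roh_chrom(chrom, pos, calls, params: RohParams) -> list[RohRegion]:
    n = len(calls)
    is_hom = [c in HOM_CALLS for c in calls]
    is_het = [c == HET_CALL for c in calls]
    is_mis = [c == MISSING_CALL for c in calls]

    out: list[RohRegion] = []
    last_j = -1  # right edge (trimmed) of the last maximal window seen
    j = -1
    het = mis = 0  # counts over the current window [i, j]
    for i in range(n):
        if j < i:  # window fell behind the left edge: restart at i
            j, het, mis = i, int(is_het[i]), int(is_mis[i])
        if is_hom[i]:
            # greedily extend the right edge while counts stay within bounds
            while j + 1 < n:
                nh = het + is_het[j + 1]
                nm = mis + is_mis[j + 1]
                if nh > params.max_het or nm > params.max_missing:
                    break
                j += 1
                het, mis = nh, nm
            # trim the right edge to the outermost homozygous marker
            jt = j
            while jt >= i and not is_hom[jt]:
                jt -= 1
            if jt > last_j:  # otherwise contained in an earlier maximal window
                if (jt - i + 1) >= params.min_markers and (
                    pos[jt] - pos[i]
                ) >= params.min_length_bp:
                    out.append(
                        RohRegion(
                            chrom=chrom,
                            start=int(pos[i]),
                            end=int(pos[jt]),
                            n_markers=jt - i + 1,
                            n_het_tolerated=sum(is_het[i : jt + 1]),
                        )
                    )
                last_j = jt
        # slide: drop marker i from the window before advancing the left edge
        het -= is_het[i]
        mis -= is_mis[i]
    return out


def intersect_shared(
    regions_per_sample: list[list[RohRegion]],
    genotypes: GenotypeMatrix | None = None,
) -> list[RohRegion]:
    """Maximal intervals contained in at least one ROH of *every* sample.

    Sharing requires positional overlap only, not allele identity. If the
    genotype matrix is supplied, marker counts are recomputed over each
    intersection.
    """
    if len(regions_per_sample) < 2:
        raise ValueError("need ROH lists from at least 2 samples")

    def as_intervals(regions):
        """Per-chromosome union of a sample's (possibly overlapping) runs."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        merged = {}
        for c, ivals in by_chrom.items():
            ivals.sort()
            out = [list(ivals[0])]
            for s, e in ivals[1:]:
                if s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[c] = [(s, e) for s, e in out]
        return merged

    current = as_intervals(regions_per_sample[0])
    for regions in regions_per_sample[1:]:
        nxt = as_intervals(regions)
        merged: dict[str, list[tuple[int, int]]] = {}
        for chrom in set(current) & set(nxt):
            a, b = current[chrom], nxt[chrom]
            res, i, j = [], 0, 0
            while i < len(a) and j < len(b):
                lo = max(a[i][0], b[j][0])
                hi = min(a[i][1], b[j][1])
                if lo <= hi:
                    res.append((lo, hi))
                if a[i][1] < b[j][1]:
                    i += 1
                else:
                    j += 1
            if res:
                merged[chrom] = res
        current = merged

    out = []
    for chrom in sorted(current):
        for lo, hi in current[chrom]:
            n = genotypes.count_markers_in(chrom, lo, hi) if genotypes else 0
            out.append(RohRegion(chrom=chrom, start=lo, end=hi, n_markers=n))
    return out


def write_regions_bed(regions: list[RohRegion], path: str | Path) -> None:
    """BED output (0-based half-open)."""
    lines = [f"{r.chrom}\t{r.start - 1}\t{r.end}" for r in regions]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_regions_tsv(regions: list[RohRegion], path: str | Path) -> None:
    header = "chrom\tstart\tend\tsize_mb\tn_markers\tn_het_tolerated"
    lines = [header] + [
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.size_mb}\t{r.n_markers}\t{r.n_het_tolerated}"
        for r in regions
    ]
    Path(path).write_text("\n".join(lines) + "\n")
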