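"""Genotype encoding, marker filtering, IBS and homogeneous-line removal.

Synchronized variants and ORFS calls become samples x markers matrices coded
0 (reference / conserved), 1 (alternate / interrupted) or -1 (missing) for a
haploid or inbred population.  Marker identity for INDELs is
(position, length, type): two insertions of equal length at one anchor are
one marker even when the inserted text differs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

PRESETS = {
    "athaliana": {"maf_min": 0.10, "miss_max": 0.5, "mac_min": 5},
    "dmelanogaster": {"maf_min": 0.05, "miss_max": 0.2, "mac_min": 8},
}


@dataclass
class GenotypeMatrix:
    """Samples x markers genotypes in {0, 1, -1(missing)} for one variant class."""

    samples: list[str]
    markers: pd.DataFrame  # chrom, pos, kind, length, allele
    values: np.ndarray  # int8, samples x markers

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.samples), len(self.markers)):
            raise ValueError("genotype matrix shape mismatch")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_rate(self) -> np.ndarray:
        return (self.values == MISSING).mean(axis=0)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        ones = (self.values == 1).sum(axis=0)
        zeros = (self.values == 0).sum(axis=0)
        return zeros, ones

    def maf(self) -> np.ndarray:
        zeros, ones = self.allele_counts()
        called = zeros + ones
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(called > 0, ones / np.maximum(called, 1), 0.0)
        return np.minimum(freq, 1.0 - freq)

    def mac(self) -> np.ndarray:
        zeros, ones = self.allele_counts()
        return np.minimum(zeros, ones)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            self.markers.iloc[keep].reset_index(drop=True),
            self.values[:, keep],
        )

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(list(keep), self.markers.copy(), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{r.chrom}:{r.pos}:{r.kind}:{r.length}" for r in self.markers.itertuples()
        ]
        return pd.DataFrame(self.values, index=self.samples, columns=cols)


def _sample_indel_spans(sync_result) -> dict[str, dict[str, list]]:
    """Per sample and chrom, reference spans + identity keys of its INDELs."""
    spans: dict[str, dict[str, list]] = {}
    for sample, vs in sync_result.varsets.items():
        per_chrom: dict[str, list] = {}
        for chrom, calls in vs.calls.items():
            for c in calls:
                if not c.is_indel:
                    continue
                if c.is_insertion:
                    key = (chrom, c.pos, "ins", len(c.alt_allele))
                    per_chrom.setdefault(chrom, []).append((c.pos, c.pos, key))
                else:
                    key = (chrom, c.pos, "del", len(c.ref_allele))
                    per_chrom.setdefault(chrom, []).append((c.pos, c.end, key))
        spans[sample] = per_chrom
    return spans


def encode_snps(
    sync_result,
    input_varsets: list | None = None,
    min_support: int = 2,
) -> GenotypeMatrix:
    """Biallelic SNP matrix with the three per-sample missingness rules.

    A sample is missing at a SNP when (1) its input call there has read
    support below ``min_support``, (2) the call is heterozygous, or (3) the
    position is physically overlapped by one of the sample's deletions.
    Support and heterozygosity vacuously pass when the input carries no such
    fields.
    """
    markers = sync_result.markers
    snp_rows = markers.index[markers.kind == "snp"]
    # biallelic within the population: exactly one alternate allele per site
    site_counts = markers.loc[snp_rows].groupby(["chrom", "pos"]).size()
    biallelic = {site for site, cnt in site_counts.items() if cnt == 1}
    keep = [i for i in snp_rows if (markers.chrom[i], markers.pos[i]) in biallelic]
    samples = sync_result.samples
    values = sync_result.genotypes[:, keep].astype(np.int8).copy()
    sub = markers.iloc[keep].reset_index(drop=True)
    sub = sub.assign(allele=sub.alt)[["chrom", "pos", "kind", "length", "allele"]]

    # rule (3): deletion spans of each sample
    for si, sample in enumerate(samples):
        vs = sync_result.varsets[sample]
        for chrom, calls in vs.calls.items():
            dels = [(c.pos, c.end) for c in calls if c.is_deletion]
            if not dels:
                continue
            in_chrom = sub.index[sub.chrom == chrom].to_numpy()
            pos = sub.pos.values[in_chrom]
            for ds, de in dels:
                hit = in_chrom[(pos >= ds) & (pos < de)]
                values[si, hit] = MISSING

    # rules (1) and (2): support / heterozygosity from the input calls
    if input_varsets is not None:
        marker_index = {
            (r.chrom, r.pos): i for i, r in enumerate(sub.itertuples(index=False))
        }
        for si, vs in enumerate(input_varsets):
            for chrom, calls in vs.calls.items():
                for c in calls:
                    if not c.is_snp:
                        continue
                    mi = marker_index.get((chrom, c.pos))
                    if mi is None:
                        continue
                    if c.support is not None and c.support < min_support:
                        values[si, mi] = MISSING
                    if c.het:
                        values[si, mi] = MISSING
    return GenotypeMatrix(list(samples), sub, values)


def encode_indels(sync_result) -> GenotypeMatrix:
    """INDEL matrix keyed by (position, length, type).

    A non-carrier is missing at a marker when a *different* INDEL of its own
    occupies part of the marker's positions (for insertion markers: a
    deletion covering the anchor, or a different-length insertion at the
    same anchor).  Carriers stay 1: overlapping INDELs are independent
    records.
    """
    markers = sync_result.markers
    keep = markers.index[markers.kind.isin(["ins", "del"])].to_numpy()
    samples = sync_result.samples
    values = sync_result.genotypes[:, keep].astype(np.int8).copy()
    sub = markers.iloc[keep].reset_index(drop=True)
    sub = sub.assign(allele=sub.alt)[["chrom", "pos", "kind", "length", "allele"]]
    spans = _sample_indel_spans(sync_result)

    for si, sample in enumerate(samples):
        for chrom, own in spans[sample].items():
            in_chrom = sub.index[sub.chrom == chrom].to_numpy()
            if len(in_chrom) == 0:
                continue
            mpos = sub.pos.values[in_chrom]
            mlen = sub.length.values[in_chrom]
            mkind = sub.kind.values[in_chrom]
            mend = np.where(mkind == "del", mpos + mlen, mpos)
            for os_, oe, okey in own:
                okind = okey[2]
                if okind == "del":
                    overlap = (mkind == "del") & (mpos < oe) & (mend > os_)
                    ins_inside = (mkind == "ins") & (mpos > os_) & (mpos < oe)
                    hit = overlap | ins_inside
                else:  # own insertion anchored at point os_
                    same_anchor = (mkind == "ins") & (mpos == os_)
                    del_cover = (mkind == "del") & (mpos < os_) & (mend > os_)
                    hit = same_anchor | del_cover
                own_marker = (mpos == okey[1]) & (mkind == okind) & (mlen == okey[3])
                idx = in_chrom[hit & ~own_marker]
                non_carrier = values[si, idx] != 1
                values[si, idx[non_carrier]] = MISSING
    return GenotypeMatrix(list(samples), sub, values)


def encode_orfs(orfs_matrix: pd.DataFrame) -> GenotypeMatrix:
    """ORFS matrix (genes x samples, 0/1/NaN) -> GenotypeMatrix (samples x genes)."""
    samples = list(orfs_matrix.columns)
    values = orfs_matrix.T.to_numpy(dtype=float)
    coded = np.where(np.isnan(values), MISSING, values).astype(np.int8)
    markers = pd.DataFrame(
        {
            "chrom": ["gene"] * orfs_matrix.shape[0],
            "pos": np.arange(orfs_matrix.shape[0]),
            "kind": "orfs",
            "length": 1,
            "allele": list(orfs_matrix.index),
        }
    )
    return GenotypeMatrix(samples, markers, coded)


def filter_markers(
    gm: GenotypeMatrix,
    maf_min: float = 0.1,
    miss_max: float = 0.5,
    mac_min: int = 5,
    exclude: list[tuple[str, int, int]] | None = None,
    return_log: bool = False,
):
    """Drop markers failing MAF / missing-rate / minor-allele-count thresholds
    or falling inside excluded regions.  MAF is computed over non-missing
    samples only."""
    maf = gm.maf()
    miss = gm.missing_rate()
    mac = gm.mac()
    ok = (maf >= maf_min) & (miss <= miss_max) & (mac >= mac_min)
    n_excluded = 0
    if exclude:
        inside = np.zeros(gm.n_markers, dtype=bool)
        pos = gm.markers.pos.values
        chroms = gm.markers.chrom.values
        for chrom, start, end in exclude:
            inside |= (chroms == chrom) & (pos >= start) & (pos < end)
        n_excluded = int((ok & inside).sum())
        ok &= ~inside
    log = {
        "n_input": gm.n_markers,
        "n_maf": int((maf < maf_min).sum()),
        "n_miss": int((miss > miss_max).sum()),
        "n_mac": int((mac < mac_min).sum()),
        "n_excluded_region": n_excluded,
        "n_kept": int(ok.sum()),
    }
    out = gm.subset_markers(np.flatnonzero(ok))
    return (out, log) if return_log else out


# ---------------------------------------------------------------------------
# IBS and homogeneous lines
# ---------------------------------------------------------------------------


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix,
    window_bp: int = 2000,
    step_bp: int = 1000,
    r2_max: float = 0.9,
) -> GenotypeMatrix:
    """Sliding-window LD pruning: within each window drop the later-position
    SNP of any pair with r^2 above the threshold."""
    dropped = np.zeros(gm.n_markers, dtype=bool)
    for chrom in gm.markers.chrom.unique():
        idx = gm.markers.index[gm.markers.chrom == chrom].to_numpy()
        pos = gm.markers.pos.values[idx]
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        if len(idx) == 0:
            continue
        for ws in range(0, int(pos.max()) + 1, step_bp):
            in_win = idx[(pos >= ws) & (pos < ws + window_bp)]
            for a in range(len(in_win)):
                ia = in_win[a]
                if dropped[ia]:
                    continue
                for b in range(a + 1, len(in_win)):
                    ib = in_win[b]
                    if dropped[ib]:
                        continue
                    if _pairwise_r2(gm.values[:, ia], gm.values[:, ib]) > r2_max:
                        dropped[ib] = True
    return gm.subset_markers(np.flatnonzero(~dropped))


def ibs_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state: fraction of co-non-missing markers with identical
    alleles, per sample pair.  Symmetric with unit diagonal."""
    n = len(gm.samples)
    vals = gm.values
    ibs = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (vals[i] != MISSING) & (vals[j] != MISSING)
            total = int(ok.sum())
            if total == 0:
                ibs[i, j] = ibs[j, i] = 0.0
            else:
                same = int((vals[i, ok] == vals[j, ok]).sum())
                ibs[i, j] = ibs[j, i] = same / total
    return pd.DataFrame(ibs, index=gm.samples, columns=gm.samples)


def remove_homogeneous(
    ibs: pd.DataFrame,
    quality: dict[str, float],
    duplicate_flags: dict[str, bool] | None = None,
    threshold: float = 0.9,
) -> list[str]:
    """Keep one sample per homogeneous group (connected component of the
    IBS > threshold graph): samples flagged as id-duplicates are removed
    preferentially, then the highest trustable-ORFS count (a proxy for
    sequencing quality) wins; remaining ties keep the earliest sample."""
    import networkx as nx

    duplicate_flags = duplicate_flags or {}
    samples = list(ibs.index)
    g = nx.Graph()
    g.add_nodes_from(samples)
    arr = ibs.values
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            if arr[i, j] > threshold:
                g.add_edge(samples[i], samples[j])
    retained = []
    order = {s: k for k, s in enumerate(samples)}
    for comp in nx.connected_components(g):
        members = sorted(comp, key=order.get)
        candidates = [s for s in members if not duplicate_flags.get(s, False)] or members
        best = max(candidates, key=lambda s: (quality.get(s, 0.0), -order[s]))
        retained.append(best)
    return sorted(retained, key=order.get)
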