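"""Readers and writers for the formats the pipeline touches.

VCF v4.2 (GT/DP subset, via pysam), BEAGLE genotype-likelihood text,
two-column population maps, TSV distance matrices, and Newick dendrograms.
Internally genotype likelihoods are natural-log values; BEAGLE files hold
linear-scale triples rescaled so the per-entry maximum is 1, per that
format's convention.  Readers reject malformed input rather than coerce it.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.cluster.hierarchy import to_tree

from .containers import (
    MISSING,
    DistanceMatrix,
    GenotypeLikelihoodTensor,
    GenotypeMatrix,
    PopulationMap,
    make_site_table,
)

__all__ = [
    "VcfParseError",
    "BeagleParseError",
    "read_vcf",
    "write_vcf",
    "read_beagle_gl",
    "write_beagle_gl",
    "read_popmap",
    "write_popmap",
    "write_distance_tsv",
    "read_distance_tsv",
    "linkage_to_newick",
    "write_true_freqs",
]

_BASE_CODE = {"A": "0", "C": "1", "G": "2", "T": "3"}
_CODE_BASE = {v: k for k, v in _BASE_CODE.items()}

#: floor applied when mapping linear BEAGLE values back to log space
_LOG_FLOOR = -700.0


class VcfParseError(ValueError):
    pass


class BeagleParseError(ValueError):
    pass


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Parse a VCF v4.2 file into a :class:`GenotypeMatrix`.

    Diploid GTs map to dosages (0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2,
    ./. -> missing; phased separators accepted).  Records with more than one
    ALT allele, indel alleles, or non-diploid calls are retained with flags
    set and their dosages marked missing, so the filter stage can account
    for them explicitly.
    """
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed or unreadable VCF header: {exc}") from exc

    samples = list(vf.header.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    f_indel: list[bool] = []
    f_multi: list[bool] = []
    f_ploidy: list[bool] = []
    dosage_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    any_depth = False

    try:
        records = list(vf)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF record: {exc}") from exc

    for rec_no, rec in enumerate(records, start=1):
        rec_alts = tuple(a for a in (rec.alts or ()) if a is not None)
        multi = len(rec_alts) > 1
        alt = ",".join(rec_alts) if rec_alts else "."
        indel = len(rec.ref) != 1 or any(len(a) != 1 for a in rec_alts)
        bad_ploidy = False

        dos = np.full(len(samples), MISSING, dtype=np.int8)
        dep = np.full(len(samples), MISSING, dtype=np.int32)
        for i, s in enumerate(samples):
            call = rec.samples[s]
            gt = call.get("GT")
            dp = call.get("DP")
            if dp is not None:
                dep[i] = dp
                any_depth = True
            if gt is None or all(a is None for a in gt):
                continue
            if len(gt) != 2 or any(a is None for a in gt):
                bad_ploidy = True
                continue
            if any(a > 1 for a in gt):
                # allele beyond the first ALT: only defined for flagged
                # multi-allelic records; dosage stays missing
                continue
            dos[i] = gt[0] + gt[1]
        if multi or indel or bad_ploidy:
            dos[:] = MISSING

        chroms.append(rec.chrom)
        positions.append(rec.pos)
        refs.append(rec.ref)
        alts.append(alt)
        f_indel.append(indel)
        f_multi.append(multi)
        f_ploidy.append(bad_ploidy)
        dosage_rows.append(dos)
        depth_rows.append(dep)

    n_sites = len(positions)
    sites = make_site_table(
        chroms, positions, refs, alts,
        is_indel=f_indel, is_multiallelic=f_multi, is_bad_ploidy=f_ploidy,
    )
    dosage = (
        np.stack(dosage_rows, axis=1) if n_sites else np.empty((len(samples), 0), np.int8)
    )
    depth = (
        np.stack(depth_rows, axis=1) if n_sites else np.empty((len(samples), 0), np.int32)
    )
    return GenotypeMatrix(
        samples=samples, sites=sites, dosage=dosage,
        depth=depth if any_depth else None,
    )


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a :class:`GenotypeMatrix` as VCF v4.2 with GT (and DP) fields.

    Missing genotypes are emitted as ``./.``; dosage 1 is always ``0/1``.
    """
    header = pysam.VariantHeader()
    for chrom in pd.unique(matrix.sites["chrom"]):
        header.add_line(f"##contig=<ID={chrom}>")
    header.formats.add("GT", 1, "String", "Genotype")
    if matrix.depth is not None:
        header.formats.add("DP", 1, "Integer", "Read depth")
    for s in matrix.samples:
        header.add_sample(s)

    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for j, site in enumerate(matrix.sites.itertuples()):
            alleles = (site.ref, *site.alt.split(","))
            rec = out.new_record(contig=site.chrom, start=site.pos - 1, alleles=alleles)
            for i, s in enumerate(matrix.samples):
                rec.samples[s]["GT"] = gt_of[int(matrix.dosage[i, j])]
                rec.samples[s].phased = False
                if matrix.depth is not None and matrix.depth[i, j] != MISSING:
                    rec.samples[s]["DP"] = int(matrix.depth[i, j])
            out.write(rec)


def write_beagle_gl(tensor: GenotypeLikelihoodTensor, path: str | os.PathLike) -> None:
    """Write BEAGLE genotype-likelihood text (3 columns per individual).

    Each non-missing triple is rescaled to a maximum of 1 on the linear
    scale; missing entries are written as three zeros.
    """
    with open(path, "w") as fh:
        head = ["marker", "allele1", "allele2"]
        for s in tensor.samples:
            head += [s, s, s]
        fh.write("\t".join(head) + "\n")
        lin = np.exp(tensor.loglik - tensor.loglik.max(axis=2, keepdims=True))
        lin[tensor.missing] = 0.0
        for j, site in enumerate(tensor.sites.itertuples()):
            row = [
                f"{site.chrom}_{site.pos}",
                _BASE_CODE.get(site.ref, site.ref),
                _BASE_CODE.get(site.alt, site.alt),
            ]
            for i in range(tensor.n_samples):
                row += [f"{v:.6f}" for v in lin[i, j]]
            fh.write("\t".join(row) + "\n")


def read_beagle_gl(path: str | os.PathLike) -> GenotypeLikelihoodTensor:
    """Parse a BEAGLE likelihood file; all-zero triples become missing."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise BeagleParseError(f"{path}: empty file")
    head = lines[0].split("\t")
    if len(head) < 6 or (len(head) - 3) % 3 != 0:
        raise BeagleParseError(
            f"{path}: line 1: expected 'marker allele1 allele2' plus 3 columns per sample"
        )
    samples = head[3::3]
    n = len(samples)
    if head[3:] != [s for s in samples for _ in range(3)]:
        raise BeagleParseError(f"{path}: line 1: sample columns must come in identical triples")

    chroms, positions, refs, alts = [], [], [], []
    logliks, missings = [], []
    for ln_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3 + 3 * n:
            raise BeagleParseError(
                f"{path}: line {ln_no}: expected {3 + 3 * n} columns, found {len(fields)}"
            )
        marker = fields[0]
        if "_" not in marker:
            raise BeagleParseError(f"{path}: line {ln_no}: marker {marker!r} is not CHROM_POS")
        chrom, pos = marker.rsplit("_", 1)
        try:
            pos_i = int(pos)
            vals = np.asarray([float(v) for v in fields[3:]], dtype=float).reshape(n, 3)
        except ValueError as exc:
            raise BeagleParseError(f"{path}: line {ln_no}: {exc}") from exc
        if (vals < 0).any():
            raise BeagleParseError(f"{path}: line {ln_no}: negative likelihood")
        miss = vals.sum(axis=1) == 0.0
        with np.errstate(divide="ignore"):
            ll = np.where(vals > 0, np.log(np.maximum(vals, 1e-300)), _LOG_FLOOR)
        ll[miss] = 0.0
        chroms.append(chrom)
        positions.append(pos_i)
        refs.append(_CODE_BASE.get(fields[1], fields[1]))
        alts.append(_CODE_BASE.get(fields[2], fields[2]))
        logliks.append(ll)
        missings.append(miss)

    sites = make_site_table(chroms, positions, refs, alts)
    m = len(positions)
    return GenotypeLikelihoodTensor(
        samples=samples,
        sites=sites,
        loglik=np.stack(logliks, axis=1) if m else np.empty((n, 0, 3)),
        missing=np.stack(missings, axis=1) if m else np.empty((n, 0), bool),
    )


def read_popmap(path: str | os.PathLike) -> PopulationMap:
    """Read a two-column TSV of (sample, population)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {ln_no}: expected 2 tab-separated columns")
            sample, pop = fields
            if sample in mapping:
                raise ValueError(f"{path}: line {ln_no}: duplicate sample {sample!r}")
            mapping[sample] = pop
    return PopulationMap(mapping)


def write_popmap(popmap: PopulationMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


def write_distance_tsv(dm: DistanceMatrix, path: str | os.PathLike) -> None:
    dm.to_frame().to_csv(path, sep="\t", index_label="sample")


def read_distance_tsv(path: str | os.PathLike) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    d = df.to_numpy(dtype=float)
    return DistanceMatrix(
        samples=list(df.columns), d=d, n_shared_sites=np.zeros_like(d, dtype=np.int64)
    )


def linkage_to_newick(linkage_matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string.

    Branch lengths are half the difference between successive merge heights,
    so tip-to-ancestor path lengths reproduce half the cophenetic distance
    (the usual ultrametric dendrogram convention).
    """
    tree = to_tree(linkage_matrix)

    def fmt(node, parent_height: float) -> str:
        length = (parent_height - node.dist) / 2.0
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    inner = fmt(tree, tree.dist)
    # root carries zero-length stem
    return inner.rsplit(":", 1)[0] + ";"


def write_true_freqs(true_freqs: np.ndarray, deme_names: Sequence[str], sites, path) -> None:
    """Write the simulator's true per-deme allele frequencies as TSV."""
    rows = []
    for i, name in enumerate(deme_names):
        for j, site in enumerate(sites.itertuples()):
            rows.append((f"{site.chrom}_{site.pos}", name, true_freqs[i, j]))
    pd.DataFrame(rows, columns=["site", "deme", "true_freq"]).to_csv(
        path, sep="\t", index=False
    )
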