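"""In-memory containers shared across the pipeline.

Genotypes are stored as alt-allele dosages (0, 1, 2) with ``MISSING`` (-1)
for no-calls; site metadata lives in a pandas DataFrame with one row per
site.  Coordinates are 0-based internally; the VCF layer converts to/from
1-based positions at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: sentinel for missing dosage / depth entries
MISSING: int = -1

#: columns every site table carries
SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "is_indel", "is_multiallelic", "is_bad_ploidy")


def make_site_table(
    chrom: Sequence[str],
    pos: Sequence[int],
    ref: Sequence[str],
    alt: Sequence[str],
    *,
    is_indel: Sequence[bool] | None = None,
    is_multiallelic: Sequence[bool] | None = None,
    is_bad_ploidy: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Assemble a site table with the canonical columns and dtypes."""
    n = len(pos)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chrom, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "ref": pd.Series(ref, dtype=str),
            "alt": pd.Series(alt, dtype=str),
            "is_indel": pd.Series(is_indel if is_indel is not None else np.zeros(n, bool)),
            "is_multiallelic": pd.Series(
                is_multiallelic if is_multiallelic is not None else np.zeros(n, bool)
            ),
            "is_bad_ploidy": pd.Series(
                is_bad_ploidy if is_bad_ploidy is not None else np.zeros(n, bool)
            ),
        }
    )
    if (df["pos"] < 1).any():
        raise ValueError("site positions must be >= 1 (VCF convention)")
    return df


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosages for ``samples`` x ``sites``.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    sites
        Site table (see :func:`make_site_table`).
    dosage
        ``(n_samples, n_sites)`` int8 array in {0, 1, 2, MISSING}.
    depth
        Optional ``(n_samples, n_sites)`` read-depth array (MISSING where
        unknown).  ``None`` when the data source carries no depth.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or MISSING")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.dosage.shape:
                raise ValueError("depth shape must match dosage shape")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the genotype is a no-call."""
        return self.dosage == MISSING

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given site indices (bool mask or int index)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=self.samples,
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
            depth=None if self.depth is None else self.depth[:, index],
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in names]
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites,
            dosage=self.dosage[idx],
            depth=None if self.depth is None else self.depth[idx],
        )

    def allele_frequency(self) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing genotypes (NaN if none)."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        n = 2 * d.count(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = d.sum(axis=0).filled(0) / np.where(n == 0, np.nan, n)
        return np.asarray(freq, dtype=float)


@dataclass
class GenotypeLikelihoodTensor:
    """Per-genotype likelihoods (hom-ref, het, hom-alt) stored as natural logs.

    ``loglik`` has shape ``(n_samples, n_sites, 3)``; entries for missing
    observations are 0.0 (a flat likelihood) and flagged in ``missing``.
    Values need not be normalised.
    """

    samples: list[str]
    sites: pd.DataFrame
    loglik: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.loglik = np.asarray(self.loglik, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        expect = (len(self.samples), len(self.sites), 3)
        if self.loglik.shape != expect:
            raise ValueError(f"loglik shape {self.loglik.shape} != {expect}")
        if self.missing.shape != expect[:2]:
            raise ValueError("missing mask shape must be (n_samples, n_sites)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take_sites(self, index: np.ndarray) -> "GenotypeLikelihoodTensor":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeLikelihoodTensor(
            samples=self.samples,
            sites=self.sites.iloc[index].reset_index(drop=True),
            loglik=self.loglik[:, index],
            missing=self.missing[:, index],
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeLikelihoodTensor":
        idx = [self.samples.index(s) for s in names]
        return GenotypeLikelihoodTensor(
            samples=[self.samples[i] for i in idx],
            sites=self.sites,
            loglik=self.loglik[idx],
            missing=self.missing[idx],
        )


class PopulationMap:
    """Mapping from sample name to population (deme / cave) label."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map = dict(mapping)
        if not self._map:
            raise ValueError("population map is empty")

    def __getitem__(self, sample: str) -> str:
        return self._map[sample]

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, sample: str) -> bool:
        return sample in self._map

    def items(self):
        return self._map.items()

    @property
    def samples(self) -> list[str]:
        return list(self._map)

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self._map.values():
            seen.setdefault(p)
        return list(seen)

    def labels(self, samples: Iterable[str]) -> np.ndarray:
        """Label array aligned to ``samples``; raises on unmapped samples."""
        out = []
        for s in samples:
            if s not in self._map:
                raise KeyError(f"sample {s!r} has no population assignment")
            out.append(self._map[s])
        return np.asarray(out, dtype=object)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self._map.items() if p == population]

    def validate_against(self, samples: Sequence[str]) -> None:
        missing = [s for s in samples if s not in self._map]
        if missing:
            raise ValueError(f"samples absent from population map: {missing}")


@dataclass
class DistanceMatrix:
    """Pairwise IBS distances with the per-pair shared-site counts."""

    samples: list[str]
    d: np.ndarray
    n_shared_sites: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.n_shared_sites = np.asarray(self.n_shared_sites, dtype=np.int64)
        n = len(self.samples)
        if self.d.shape != (n, n) or self.n_shared_sites.shape != (n, n):
            raise ValueError("distance matrices must be square over samples")
        if not np.allclose(np.diag(self.d), 0, equal_nan=True):
            raise ValueError("distance diagonal must be zero")

    @property
    def has_undefined(self) -> bool:
        off = ~np.eye(len(self.samples), dtype=bool)
        return bool(np.isnan(self.d[off]).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.samples, columns=self.samples)
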