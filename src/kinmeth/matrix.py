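"""Core in-memory containers for sites-by-samples methylation count data.

The central object is :class:`MethylationMatrix`: a sites x samples table of
(methylated count, total count) pairs together with site coordinates and
per-sample metadata.  Missing cells (a CpG not covered in a sample's library)
are distinct from observed zero counts and are encoded as ``total == MISSING``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel total count marking a cell with no observation for that sample
MISSING = -1

VALID_GROUPS = ("hatchery", "stream")
VALID_TIMEPOINTS = ("age1", "age2")
VALID_TISSUES = ("liver", "sperm")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced individual/library."""

    sample_id: str
    group: str = "hatchery"
    timepoint: str = "age1"
    tissue: str = "liver"
    family_id: str = "unknown"

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"unknown rearing group {self.group!r}")
        if self.timepoint not in VALID_TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.tissue not in VALID_TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")


@dataclass
class MethylationMatrix:
    """Sites x samples matrix of methylation counts.

    Attributes
    ----------
    sites : pandas.DataFrame
        Columns ``chrom`` (str), ``pos`` (1-based int), ``strand``
        ({'+', '-', '.'}), sorted by (chrom, pos).
    samples : list of SampleMeta
        Column order of the count arrays.
    meth, total : numpy.ndarray of int64, shape (n_sites, n_samples)
        Methylated and total read counts.  ``total == MISSING`` marks a
        missing cell (then ``meth`` is also MISSING).
    """

    sites: pd.DataFrame
    samples: list
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.meth.shape != self.total.shape:
            raise ValueError("meth/total shape mismatch")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count array shape does not match sites/samples")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in sample list")
        obs = self.total != MISSING
        if np.any(self.total[obs] <= 0):
            raise ValueError("observed cells must have total count >= 1")
        if np.any(self.meth[obs] < 0) or np.any(self.meth[obs] > self.total[obs]):
            raise ValueError("need 0 <= n_meth <= n_total at every observed cell")
        if not self._sites_sorted():
            order = self.sites.sort_values(["chrom", "pos"], kind="mergesort").index
            self.sites = self.sites.loc[order].reset_index(drop=True)
            self.meth = self.meth[np.asarray(order)]
            self.total = self.total[np.asarray(order)]

    def _sites_sorted(self) -> bool:
        c = self.sites["chrom"].to_numpy()
        p = self.sites["pos"].to_numpy()
        for i in range(1, len(c)):
            if (c[i], p[i]) < (c[i - 1], p[i - 1]):
                return False
        return True

    # -- basic accessors -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    def observed(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) cells."""
        return self.total != MISSING

    def proportions(self) -> np.ndarray:
        """Per-cell methylation proportion; NaN at missing cells."""
        obs = self.observed()
        out = np.full(self.meth.shape, np.nan)
        out[obs] = self.meth[obs] / self.total[obs]
        return out

    # -- subsetting ------------------------------------------------------

    def subset_sites(self, mask: np.ndarray) -> "MethylationMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return MethylationMatrix(
            self.sites.iloc[idx].reset_index(drop=True),
            list(self.samples),
            self.meth[idx].copy(),
            self.total[idx].copy(),
        )

    def subset_samples(self, which) -> "MethylationMatrix":
        """Subset columns by indices, boolean mask, or sample ids."""
        if len(which) and isinstance(next(iter(which)), str):
            lut = {sid: j for j, sid in enumerate(self.sample_ids)}
            idx = np.array([lut[w] for w in which], dtype=int)
        else:
            which = np.asarray(which)
            idx = np.flatnonzero(which) if which.dtype == bool else which
        return MethylationMatrix(
            self.sites.copy(),
            [self.samples[j] for j in idx],
            self.meth[:, idx].copy(),
            self.total[:, idx].copy(),
        )

    def group_indicator(self, field_name: str, one_level: str) -> np.ndarray:
        """0/1 vector over samples: 1 where the metadata field equals one_level."""
        return np.array(
            [1.0 if getattr(s, field_name) == one_level else 0.0 for s in self.samples]
        )
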