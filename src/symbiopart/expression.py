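"""Count-matrix I/O, CPM, low-expression filtering, and TMM normalization.

The count matrix is transcripts x samples with integer entries and a
worker/soldier caste label per sample.  Normalization follows the trimmed
mean of M-values (TMM) scheme: per-sample scaling factors computed from
doubly trimmed, precision-weighted log expression ratios against a
reference sample, rescaled to geometric mean one.  The TMM expression
matrix (counts per million of the effective library size) feeds every
downstream stage — differential abundance offsets, biomarker regression
and co-expression networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

WORKER = "worker"
SOLDIER = "soldier"


@dataclass
class CountMatrix:
    """Integer transcript x sample counts with caste labels.

    ``counts`` is a DataFrame indexed by transcript id with one column per
    sample; ``castes`` maps sample id -> caste label and covers every
    column.
    """

    counts: pd.DataFrame
    castes: pd.Series

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.castes.index)
        if missing:
            raise ValueError(f"samples without caste label: {sorted(missing)}")
        self.castes = self.castes.loc[list(self.counts.columns)]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_of(self, caste: str) -> list[str]:
        return [s for s in self.counts.columns if self.castes[s] == caste]

    @classmethod
    def from_tsv(cls, counts_path: str | Path,
                 castes_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        castes = pd.read_csv(castes_path, sep="\t", index_col=0,
                             header=None, names=["sample", "caste"])["caste"]
        return cls(counts, castes)

    def to_tsv(self, counts_path: str | Path, castes_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        self.castes.to_csv(castes_path, sep="\t", header=False)


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors with geometric mean one."""

    factors: pd.Series
    reference: str

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")

    def effective_library_sizes(self, counts: pd.DataFrame) -> pd.Series:
        return counts.sum(axis=0) * self.factors


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: x_gj / N_j * 1e6. Requires positive library sizes."""
    libsizes = counts.sum(axis=0)
    if (libsizes == 0).any():
        zero = list(libsizes.index[libsizes == 0])
        raise ValueError(f"zero library size for samples {zero}")
    return counts / libsizes * 1e6


def filter_low_expression(cm: CountMatrix, min_cpm: float = 1.0,
                          min_samples: int = 10) -> CountMatrix:
    """Keep transcripts with CPM strictly above *min_cpm* in strictly more
    than *min_samples* samples.  Samples are never dropped."""
    c = cpm(cm.counts)
    keep = (c > min_cpm).sum(axis=1) > min_samples
    return CountMatrix(cm.counts.loc[keep].copy(), cm.castes.copy())


def _tmm_factor_vs_ref(obs: np.ndarray, ref: np.ndarray,
                       logratio_trim: float, abs_trim: float) -> float:
    """TMM factor of one sample against the reference sample."""
    n_obs, n_ref = obs.sum(), ref.sum()
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no positive transcript with reference")
    o, r = obs[pos] / n_obs, ref[pos] / n_ref
    m = np.log2(o / r)                      # log expression ratio
    a = 0.5 * np.log2(o * r)                # average log abundance
    # binomial precision weights on a fixed per-million scale, so factors
    # depend only on count proportions (exactly invariant to rescaling a
    # sample's library)
    co, cr = o * 1e6, r * 1e6
    w = (1e6 - co) / (1e6 * co) + (1e6 - cr) / (1e6 * cr)

    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim), np.ceil(n * (1 - logratio_trim))
    lo_a, hi_a = np.floor(n * abs_trim), np.ceil(n * (1 - abs_trim))
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = ((rank_m > lo_m) & (rank_m <= hi_m)
            & (rank_a > lo_a) & (rank_a <= hi_a))
    if not keep.any():
        return 1.0
    f = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return float(f) if np.isfinite(f) and f > 0 else 1.0


def tmm_normalize(cm: CountMatrix, logratio_trim: float = 0.30,
                  abs_trim: float = 0.05
                  ) -> tuple[NormFactors, pd.DataFrame]:
    """Compute TMM factors and the TMM expression matrix.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper-quartile CPM.  Factors are rescaled so their geometric
    mean is one; the TMM matrix entry is x_gj / (N_j f_j) * 1e6.
    """
    counts = cm.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    c = cpm(counts)
    uq = c.quantile(0.75, axis=0)
    reference = (uq - uq.mean()).abs().idxmin()

    libsizes = counts.sum(axis=0)
    ref_arr = counts[reference].to_numpy(dtype=float)
    raw = {}
    for sample in counts.columns:
        if sample == reference:
            raw[sample] = 1.0
        else:
            raw[sample] = _tmm_factor_vs_ref(
                counts[sample].to_numpy(dtype=float), ref_arr,
                logratio_trim, abs_trim)
    f = pd.Series(raw).loc[counts.columns]
    f = f / np.exp(np.mean(np.log(f)))      # geometric mean -> 1
    factors = NormFactors(f, reference)
    tmm = counts / (libsizes * f) * 1e6
    return factors, tmm
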