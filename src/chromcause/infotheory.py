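"""Dependence measures: Parzen-window MI, CMI, and mutual information gain.

Two estimator backends are provided. The ``kernel`` backend approximates
densities by an average of Gaussian kernels centred at the samples
(Parzen windows) and estimates MI / CMI as sample averages of
log-density ratios; it handles continuous conditioners such as the
log-scale nucleosome-positioning track. The ``plugin`` backend computes
the exact empirical (plug-in) information of categorical codes from
contingency tables and is fully deterministic, which makes it the
natural backend for permutation calibration and bootstrap pipelines.

Mutual information gain, MIG(x, y; z) = MI(x, y) - CMI(x, y | z), is the
part of the dependence between two marks that is mediated by the
conditioner. A pair with large MI but near-zero MIG stays dependent when
nucleosome positioning is given - the signature of a shared hidden
regulator rather than of two separate NucPos-driven regulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import ValidationError
from .io_discretize import DiscreteMatrix, equal_frequency_codes

__all__ = [
    "KernelConfig",
    "PairDependency",
    "parzen_density",
    "mutual_information",
    "conditional_mutual_information",
    "mig",
    "pairwise_dependency_table",
]

_BANDWIDTH_FLOOR = 1e-12
_DEFAULT_Z_BINS = 5


@dataclass
class KernelConfig:
    """Gaussian Parzen-window settings.

    bandwidth_rule: "silverman" (per-dimension rule-of-thumb, the default)
        or "fixed" (use ``h`` for every dimension).
    h: window width when ``bandwidth_rule == "fixed"``.
    covariance_mode: "diagonal" uses a product kernel with per-dimension
        widths; "full" whitens with the sample covariance.
    d: optional expected dimensionality (1-3); estimates above 3 dimensions
        are not supported (the pipeline needs at most trivariate densities).
    """

    bandwidth_rule: str = "silverman"
    h: float | None = None
    covariance_mode: str = "diagonal"
    d: int | None = None

    def __post_init__(self) -> None:
        if self.bandwidth_rule not in ("silverman", "fixed"):
            raise ValidationError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        if self.bandwidth_rule == "fixed" and (self.h is None or self.h <= 0):
            raise ValidationError("fixed bandwidth requires h > 0")
        if self.covariance_mode not in ("diagonal", "full"):
            raise ValidationError(f"unknown covariance mode {self.covariance_mode!r}")
        if self.d is not None and self.d not in (1, 2, 3):
            raise ValidationError("d must be 1, 2 or 3")


@dataclass
class PairDependency:
    """MI / CMI / MIG record for one unordered pair of marks (in nats)."""

    mark_a: str
    mark_b: str
    mi: float
    cmi: float
    mig: float
    estimator: str = "plugin"

    def __post_init__(self) -> None:
        if abs(self.mig - (self.mi - self.cmi)) > 1e-9:
            raise ValidationError("mig must equal mi - cmi")


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def _silverman_widths(X: np.ndarray, d: int) -> np.ndarray:
    """Per-dimension Silverman rule-of-thumb widths for a d-dim estimate."""
    n = X.shape[0]
    sd = X.std(axis=0, ddof=1)
    factor = (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))
    return np.maximum(sd * factor, _BANDWIDTH_FLOOR)


def _widths(X: np.ndarray, cfg: KernelConfig, d: int) -> np.ndarray:
    if cfg.bandwidth_rule == "fixed":
        return np.full(X.shape[1], float(cfg.h))
    return _silverman_widths(X, d)


def _log_density(train: np.ndarray, where: np.ndarray, h: np.ndarray,
                 leave_one_out: bool = False) -> np.ndarray:
    """Log Parzen density of ``where`` points under kernels at ``train``.

    With ``leave_one_out`` the i-th evaluation excludes the i-th training
    kernel (requires train is where); this removes the self-match term
    that otherwise inflates resubstitution log-density ratios.
    """
    n, d = train.shape
    diff = where[:, None, :] / h - train[None, :, :] / h
    q = np.einsum("ijk,ijk->ij", diff, diff)
    if leave_one_out:
        np.fill_diagonal(q, np.inf)
        n_eff = n - 1
    else:
        n_eff = n
    log_norm = -0.5 * d * np.log(2.0 * np.pi) - np.sum(np.log(h))
    m = np.max(-0.5 * q, axis=1)
    s = np.log(np.sum(np.exp(-0.5 * q - m[:, None]), axis=1)) + m
    return log_norm + s - np.log(n_eff)


def parzen_density(samples: np.ndarray, query: np.ndarray,
                   cfg: KernelConfig | None = None) -> np.ndarray | float:
    """Evaluate the Gaussian Parzen density estimate at query point(s).

    The estimate is the average of Gaussian kernels centred at the
    samples; it is strictly positive everywhere. Supports d in {1, 2, 3}.
    """
    cfg = cfg or KernelConfig()
    X = _as_2d(samples)
    n, d = X.shape
    if d > 3:
        raise ValidationError(f"density estimation in d={d} > 3 is unsupported")
    if n < 2:
        raise ValidationError("need at least 2 samples")
    Q = np.atleast_2d(np.asarray(query, dtype=float))
    if Q.shape[1] != d:
        Q = Q.reshape(-1, d)
    if cfg.covariance_mode == "full" and d > 1:
        cov = np.cov(X, rowvar=False)
        try:
            L = np.linalg.cholesky(cov)
            Xw = X @ np.linalg.inv(L).T
            Qw = Q @ np.linalg.inv(L).T
            h = _widths(Xw, cfg, d)
            out = np.exp(_log_density(Xw, Qw, h)) / abs(np.linalg.det(L))
            return out if out.size > 1 else float(out[0])
        except np.linalg.LinAlgError:
            pass  # degenerate covariance: fall through to diagonal
    h = _widths(X, cfg, d)
    out = np.exp(_log_density(X, Q, h))
    return out if out.size > 1 else float(out[0])


def _plugin_mi_from_codes(a: np.ndarray, b: np.ndarray) -> float:
    """Exact empirical MI of two integer-coded variables (nats)."""
    ra = int(a.max()) + 1 if a.size else 1
    rb = int(b.max()) + 1 if b.size else 1
    n = len(a)
    if n == 0:
        return 0.0
    joint = np.bincount(a * rb + b, minlength=ra * rb).reshape(ra, rb) / n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def _require_codes(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.integer):
        xf = np.asarray(x, dtype=float)
        if not np.allclose(xf, np.round(xf)):
            raise ValidationError(f"plugin estimator needs integer categories for {name}")
        x = np.round(xf).astype(np.int64)
    if x.size and x.min() < 0:
        raise ValidationError(f"negative category code in {name}")
    return x.astype(np.int64)


def mutual_information(x: np.ndarray, y: np.ndarray,
                       cfg: KernelConfig | None = None,
                       estimator: str = "kernel") -> float:
    """MI(x, y) in nats.

    plugin: exact empirical plug-in MI on categorical codes.
    kernel: leave-one-out average of log p(x,y) / (p(x) p(y)) under
        Parzen estimates sharing one per-dimension bandwidth.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if len(x) != len(y):
        raise ValidationError(f"length mismatch: {len(x)} vs {len(y)}")
    if estimator == "plugin":
        return _plugin_mi_from_codes(_require_codes(x, "x"), _require_codes(y, "y"))
    if estimator != "kernel":
        raise ValidationError(f"unknown estimator {estimator!r}")
    if len(x) < 50:
        warnings.warn("kernel MI with fewer than 50 samples is unreliable",
                      stacklevel=2)
    cfg = cfg or KernelConfig()
    XY = np.column_stack([x, y]).astype(float)
    h = _widths(XY, cfg, d=2)
    lj = _log_density(XY, XY, h, leave_one_out=True)
    lx = _log_density(XY[:, :1], XY[:, :1], h[:1], leave_one_out=True)
    ly = _log_density(XY[:, 1:], XY[:, 1:], h[1:], leave_one_out=True)
    return float(np.mean(lj - lx - ly))


def conditional_mutual_information(x: np.ndarray, y: np.ndarray, z: np.ndarray,
                                   cfg: KernelConfig | None = None,
                                   estimator: str = "kernel",
                                   z_bins: int = _DEFAULT_Z_BINS) -> float:
    """CMI(x, y | z) in nats.

    A constant conditioner is vacuous and is dropped, so the result then
    equals MI(x, y) exactly. In plugin mode a continuous conditioner is
    discretized into ``z_bins`` equal-frequency bins first.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if not len(x) == len(y) == len(z):
        raise ValidationError("x, y, z must have equal lengths")
    if z.size and np.all(z == z[0]):
        return mutual_information(x, y, cfg=cfg, estimator=estimator)
    if estimator == "plugin":
        a = _require_codes(x, "x")
        b = _require_codes(y, "y")
        zc = np.round(z).astype(np.int64) if np.allclose(z, np.round(z)) and \
            len(np.unique(z)) <= z_bins else equal_frequency_codes(z, z_bins)
        n = len(a)
        out = 0.0
        for val in np.unique(zc):
            m = zc == val
            out += (m.sum() / n) * _plugin_mi_from_codes(a[m], b[m])
        return float(out)
    if estimator != "kernel":
        raise ValidationError(f"unknown estimator {estimator!r}")
    if len(x) < 50:
        warnings.warn("kernel CMI with fewer than 50 samples is unreliable",
                      stacklevel=2)
    cfg = cfg or KernelConfig()
    XYZ = np.column_stack([x, y, z]).astype(float)
    h = _widths(XYZ, cfg, d=3)
    lxyz = _log_density(XYZ, XYZ, h, leave_one_out=True)
    lxz = _log_density(XYZ[:, [0, 2]], XYZ[:, [0, 2]], h[[0, 2]], leave_one_out=True)
    lyz = _log_density(XYZ[:, [1, 2]], XYZ[:, [1, 2]], h[[1, 2]], leave_one_out=True)
    lz = _log_density(XYZ[:, [2]], XYZ[:, [2]], h[[2]], leave_one_out=True)
    return float(np.mean(lxyz + lz - lxz - lyz))


def mig(x: np.ndarray, y: np.ndarray, z: np.ndarray,
        cfg: KernelConfig | None = None, estimator: str = "kernel",
        mark_a: str = "x", mark_b: str = "y",
        z_bins: int = _DEFAULT_Z_BINS) -> PairDependency:
    """Mutual information gain record: MIG = MI(x,y) - CMI(x,y|z)."""
    mi_val = mutual_information(x, y, cfg=cfg, estimator=estimator)
    cmi_val = conditional_mutual_information(x, y, z, cfg=cfg,
                                             estimator=estimator, z_bins=z_bins)
    return PairDependency(mark_a=mark_a, mark_b=mark_b, mi=mi_val, cmi=cmi_val,
                          mig=mi_val - cmi_val, estimator=estimator)


def pairwise_dependency_table(d: DiscreteMatrix, nucpos: np.ndarray,
                              cfg: KernelConfig | None = None,
                              estimator: str = "plugin",
                              z_bins: int = _DEFAULT_Z_BINS) -> list[PairDependency]:
    """MI / CMI / MIG for every unordered pair of marks, given NucPos."""
    if len(d.mark_names) < 2:
        raise ValidationError("need at least 2 marks")
    nucpos = np.asarray(nucpos, dtype=float).ravel()
    if len(nucpos) != len(d.gene_ids):
        raise ValidationError("nucpos length does not match gene count")
    if estimator == "plugin":
        z: np.ndarray = equal_frequency_codes(nucpos, z_bins)
    else:
        z = nucpos
    out = []
    for i, j in combinations(range(len(d.mark_names)), 2):
        out.append(mig(d.codes[:, i], d.codes[:, j], z, cfg=cfg,
                       estimator=estimator, mark_a=d.mark_names[i],
                       mark_b=d.mark_names[j], z_bins=z_bins))
    return out
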