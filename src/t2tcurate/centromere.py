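"""Centromere inference from heterozygosity dips and Hi-C interchromosomal peaks.

Centromeres suppress recombination, which in an outbred diploid shows up as
a local dip in heterozygous-site density; they also cluster in the nucleus,
inflating a bin's Hi-C contacts with *other* chromosomes.  Neither signal
alone is decisive, so a centromere is called where the (LOESS-smoothed)
interchromosomal contact z-score peak colocalizes with the smoothed
heterozygosity minimum on the same scaffold.

The z-score of bin i on scaffold S is computed from the bin's total
contacts s_i with bins on other scaffolds: t_i = log10(s_i + 1), then
z_i = (t_i - mean_S(t)) / sd_S(t) standardized within each scaffold.

Terminal bins (5% of each scaffold end) are excluded from the peak search:
telomeres also cluster and would otherwise masquerade as centromeric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .seqio import Region


def het_window_counts(
    het_positions: dict[str, np.ndarray] | pd.DataFrame,
    scaffold_lengths: dict[str, int],
    window: int = 50_000,
) -> pd.DataFrame:
    """Count heterozygous sites per non-overlapping window (empty windows = 0).

    ``het_positions`` maps scaffold -> 1-based positions, or is a DataFrame
    with columns (scaffold, pos).
    """
    if isinstance(het_positions, pd.DataFrame):
        het_positions = {
            str(s): g["pos"].to_numpy() for s, g in het_positions.groupby("scaffold")
        }
    rows = []
    for scaffold, slen in scaffold_lengths.items():
        pos = np.asarray(het_positions.get(scaffold, []), dtype=np.int64)
        if pos.size and (pos.min() < 1 or pos.max() > slen):
            raise ValidationError(
                f"het position outside scaffold '{scaffold}' (length {slen})"
            )
        n_win = max(1, math.ceil(slen / window))
        counts = np.bincount((pos - 1) // window, minlength=n_win)
        for i in range(n_win):
            rows.append(
                (scaffold, i * window + 1, min((i + 1) * window, slen), int(counts[i]))
            )
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "value"])


def interchrom_zscores(
    matrix: np.ndarray, binmap: pd.DataFrame, sym_tol: float = 1e-8
) -> pd.DataFrame:
    """Per-bin interchromosomal contact z-scores, standardized within scaffold.

    Returns a DataFrame with columns (scaffold, start, end, raw, log, z)
    where raw is the bin's summed contacts to bins on other scaffolds.
    A scaffold whose log-sums have zero spread gets z = 0 throughout.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != matrix.shape[1] or matrix.shape[0] != len(binmap):
        raise ValidationError("matrix shape does not match bin map")
    if not np.allclose(matrix, matrix.T, atol=sym_tol, rtol=0):
        raise ValidationError("contact matrix is not symmetric within tolerance")
    scaffolds = binmap["scaffold"].to_numpy()
    # contacts to other scaffolds = total row sum minus same-scaffold sum
    raw = np.empty(len(binmap))
    for scf in pd.unique(scaffolds):
        idx = np.flatnonzero(scaffolds == scf)
        raw[idx] = matrix[idx].sum(axis=1) - matrix[np.ix_(idx, idx)].sum(axis=1)
    logt = np.log10(raw + 1.0)
    z = np.zeros(len(binmap))
    for scf in pd.unique(scaffolds):
        idx = np.flatnonzero(scaffolds == scf)
        sd = logt[idx].std()
        if sd > 0:
            z[idx] = (logt[idx] - logt[idx].mean()) / sd
    out = binmap[["scaffold", "start", "end"]].copy()
    out["raw"] = raw
    out["log"] = logt
    out["z"] = z
    return out


def loess_smooth(
    x: np.ndarray, y: np.ndarray, span: float, degree: int = 1
) -> np.ndarray:
    """LOESS: locally weighted polynomial regression with tricube weights.

    At each x_i the ``ceil(span * n)`` nearest points (by |x - x_i|) are fit
    with a degree-``degree`` polynomial, weighted by the tricube kernel
    ``(1 - (d/dmax)^3)^3``; the fitted value at x_i is returned.  ``span``
    is the fraction of points in each local neighborhood.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < span <= 1:
        raise ValidationError(f"span must be in (0, 1], got {span}")
    n = len(x)
    if n < 5:
        raise ValidationError(f"LOESS needs >= 5 points, got {n}")
    k = max(degree + 1, math.ceil(span * n))
    if k > n:
        raise ValidationError(f"neighborhood {k} exceeds number of points {n}")
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        nearest = np.argpartition(d, k - 1)[:k]
        dmax = d[nearest].max()
        if dmax == 0:
            fitted[i] = np.average(y[nearest])
            continue
        w = (1 - (d[nearest] / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        if w.sum() == 0 or np.count_nonzero(w) <= degree:
            w = w + 1e-12
        # weighted polynomial LS via sqrt-weight design matrix
        X = np.vander(x[nearest] - x[i], degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[nearest] * sw, rcond=None)
        fitted[i] = beta[0]
    return fitted


@dataclass(frozen=True)
class CentromereCall:
    scaffold: str
    interval: Region
    z_peak: float
    het_min: float
    offset_bp: int  # distance between z peak bin and het dip bin centers


def call_centromeres(
    het_track: pd.DataFrame,
    z_signal: pd.DataFrame,
    span_het: float = 0.5,
    span_z: float = 0.4,
    max_offset: int = 2_000_000,
    terminal_frac: float = 0.05,
) -> list[CentromereCall]:
    """Call one centromere per scaffold where z peak and het dip colocalize.

    Per scaffold: LOESS-smooth the interchromosomal z and the het counts
    against bin centers, exclude ``terminal_frac`` of bins at each end from
    the extremum search, and emit a call iff the smoothed-z argmax and the
    smoothed-het argmin bin centers are within ``max_offset`` bp.  Scaffolds
    where either smoothed signal is flat yield no call.
    """
    calls: list[CentromereCall] = []
    z_by = {s: g.reset_index(drop=True) for s, g in z_signal.groupby("scaffold")}
    het_by = {s: g.reset_index(drop=True) for s, g in het_track.groupby("scaffold")}
    for scaffold in sorted(z_by):
        if scaffold not in het_by:
            raise ValidationError(f"no heterozygosity track for scaffold '{scaffold}'")
        zg, hg = z_by[scaffold], het_by[scaffold]
        if len(zg) < 5 or len(hg) < 5:
            continue
        zc = (zg["start"].to_numpy() + zg["end"].to_numpy()) / 2
        hc = (hg["start"].to_numpy() + hg["end"].to_numpy()) / 2
        z_sm = loess_smooth(zc, zg["z"].to_numpy(), span_z)
        h_sm = loess_smooth(hc, hg["value"].to_numpy(), span_het)
        if np.ptp(z_sm) == 0 or np.ptp(h_sm) == 0:
            continue

        def interior(n: int) -> slice:
            drop = int(terminal_frac * n)
            return slice(drop, n - drop if drop else n)

        zi, hi = interior(len(z_sm)), interior(len(h_sm))
        z_arg = int(np.argmax(z_sm[zi])) + zi.start
        h_arg = int(np.argmin(h_sm[hi])) + hi.start
        offset = abs(int(zc[z_arg]) - int(hc[h_arg]))
        if offset > max_offset:
            continue
        start = min(int(zg["start"][z_arg]), int(hg["start"][h_arg]))
        end = max(int(zg["end"][z_arg]), int(hg["end"][h_arg]))
        calls.append(
            CentromereCall(
                scaffold=scaffold,
                interval=Region(scaffold, start, end, label="centromere"),
                z_peak=float(z_sm[z_arg]),
                het_min=float(h_sm[h_arg]),
                offset_bp=offset,
            )
        )
    return calls
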