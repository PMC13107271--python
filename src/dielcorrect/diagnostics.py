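"""MCMC convergence diagnostics: rank-normalized split R-hat and bulk ESS.

Implements the rank-normalization diagnostics of Vehtari, Gelman, Simpson,
Carpenter & Bürkner (2021): chains are split in half, draws are transformed to
normal scores through their pooled ranks, and the classic potential scale
reduction factor / autocorrelation-based effective sample size are computed on
the transformed draws. R-hat additionally takes the maximum with the folded
(|x − median|) version so both location and scale mixing failures are caught.

These are computed in-process (vectorized numpy, no per-fit container
overhead) because the replicate sweeps diagnose tens of thousands of fits.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.fft import next_fast_len
from scipy.special import ndtri

__all__ = [
    "split_rhat",
    "ess_bulk",
    "split_rhat_batch",
    "ess_bulk_batch",
    "diagnose_batch",
]


def _z_scale(ary: np.ndarray) -> np.ndarray:
    """Rank-normalize draws: pooled average ranks → normal scores (Blom offset)."""
    rank = stats.rankdata(ary, method="average")
    z = stats.norm.ppf((rank - 0.375) / (ary.size + 0.25))
    return z.reshape(ary.shape)


def _split_chains(ary: np.ndarray) -> np.ndarray:
    """Split each chain in half and stack the halves as separate chains."""
    ary = np.atleast_2d(np.asarray(ary, dtype=float))
    half = ary.shape[1] // 2
    return np.vstack([ary[:, :half], ary[:, -half:]])


def _rhat_2d(ary: np.ndarray) -> float:
    """Classic potential scale reduction factor for a (chains, draws) array."""
    _, n_draw = ary.shape
    chain_mean = ary.mean(axis=1)
    within = ary.var(axis=1, ddof=1).mean()
    between = n_draw * chain_mean.var(ddof=1)
    return float(np.sqrt((between / within + n_draw - 1) / n_draw))


def _autocov(ary: np.ndarray) -> np.ndarray:
    """Biased FFT autocovariance per chain, all lags."""
    n = ary.shape[1]
    m = next_fast_len(2 * n)
    centered = ary - ary.mean(axis=1, keepdims=True)
    fft = np.fft.rfft(centered, n=m, axis=1)
    fft *= np.conjugate(fft)
    return np.fft.irfft(fft, n=m, axis=1)[:, :n] / n


def split_rhat(draws: np.ndarray) -> float:
    """Rank-normalized split R-hat for one scalar parameter.

    Parameters
    ----------
    draws
        Array of shape ``(chains, draws)`` with at least 2 chains and
        4 draws per chain.
    """
    ary = np.atleast_2d(np.asarray(draws, dtype=float))
    if ary.shape[0] < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if ary.shape[1] < 4:
        raise ValueError("R-hat requires at least 4 draws per chain")
    split = _split_chains(ary)
    if np.ptp(split) < np.finfo(float).resolution:
        return 1.0  # constant parameter: no mixing information, treat as mixed
    bulk = _rhat_2d(_z_scale(split))
    folded = _rhat_2d(_z_scale(np.abs(split - np.median(split))))
    return max(bulk, folded)


def ess_bulk(draws: np.ndarray) -> float:
    """Bulk effective sample size (rank-normalized, split chains).

    Uses Geyer's initial positive and monotone sequence truncation of the
    combined-chain autocorrelation.
    """
    ary = np.atleast_2d(np.asarray(draws, dtype=float))
    if ary.shape[1] < 4:
        raise ValueError("ESS requires at least 4 draws per chain")
    z = _z_scale(_split_chains(ary))
    return _ess_2d(z)


def _ess_2d(ary: np.ndarray) -> float:
    if np.ptp(ary) < np.finfo(float).resolution:
        return float(ary.size)
    n_chain, n_draw = ary.shape
    acov = _autocov(ary)
    mean_var = acov[:, 0].mean() * n_draw / (n_draw - 1.0)
    var_plus = mean_var * (n_draw - 1.0) / n_draw
    if n_chain > 1:
        var_plus += ary.mean(axis=1).var(ddof=1)

    mean_acov = acov.mean(axis=0)
    rho_hat = np.zeros(n_draw)
    rho_even = 1.0
    rho_hat[0] = rho_even
    rho_odd = 1.0 - (mean_var - mean_acov[1]) / var_plus
    rho_hat[1] = rho_odd

    # Geyer initial positive sequence: stop once a paired sum turns negative
    t = 1
    while t < (n_draw - 3) and (rho_even + rho_odd) > 0.0:
        rho_even = 1.0 - (mean_var - mean_acov[t + 1]) / var_plus
        rho_odd = 1.0 - (mean_var - mean_acov[t + 2]) / var_plus
        if (rho_even + rho_odd) >= 0:
            rho_hat[t + 1] = rho_even
            rho_hat[t + 2] = rho_odd
        t += 2
    max_t = t - 2
    if rho_even > 0:
        rho_hat[max_t + 1] = rho_even

    # Geyer initial monotone sequence
    t = 1
    while t <= max_t - 2:
        if (rho_hat[t + 1] + rho_hat[t + 2]) > (rho_hat[t - 1] + rho_hat[t]):
            rho_hat[t + 1] = (rho_hat[t - 1] + rho_hat[t]) / 2.0
            rho_hat[t + 2] = rho_hat[t + 1]
        t += 2

    size = n_chain * n_draw
    tau_hat = -1.0 + 2.0 * rho_hat[: max_t + 1].sum() + rho_hat[max_t + 1]
    tau_hat = max(tau_hat, 1.0 / np.log10(size))
    return float(size / tau_hat)


# ---------------------------------------------------------------------------
# batched variants: many scalar parameters of the same fit at once
# ---------------------------------------------------------------------------


def _z_scale_rows(ary: np.ndarray) -> np.ndarray:
    """Rank-normalize each row of a 2-D array independently.

    Ranks come from a double argsort (ordinal ranks); for continuous MCMC
    draws ties have probability zero, so this equals average ranking while
    avoiding scipy's stable-sort overhead. Exactly constant rows are handled
    by the callers' constant-parameter guard.
    """
    order = np.argsort(ary, axis=1)
    rank = np.empty(ary.shape, dtype=np.float64)
    np.put_along_axis(
        rank, order, np.arange(1.0, ary.shape[1] + 1.0)[None, :], axis=1
    )
    return ndtri((rank - 0.375) / (ary.shape[1] + 0.25))


def _split_chains_batch(draws: np.ndarray) -> np.ndarray:
    """(P, C, T) → (P, 2C, T//2): halves of each chain become chains."""
    half = draws.shape[2] // 2
    return np.concatenate([draws[:, :, :half], draws[:, :, -half:]], axis=1)


def _rhat_2d_batch(ary: np.ndarray) -> np.ndarray:
    n_draw = ary.shape[2]
    chain_mean = ary.mean(axis=2)
    within = ary.var(axis=2, ddof=1).mean(axis=1)
    between = n_draw * chain_mean.var(axis=1, ddof=1)
    return np.sqrt((between / within + n_draw - 1) / n_draw)


def split_rhat_batch(draws: np.ndarray) -> np.ndarray:
    """Rank-normalized split R-hat for a (params, chains, draws) stack."""
    draws = np.asarray(draws, dtype=float)
    P, C, T = draws.shape
    if C < 2 or T < 4:
        raise ValueError("R-hat requires >= 2 chains and >= 4 draws per chain")
    split = _split_chains_batch(draws)
    flat = split.reshape(P, -1)
    constant = np.ptp(flat, axis=1) < np.finfo(float).resolution
    shape = split.shape
    z = _z_scale_rows(flat).reshape(shape)
    folded = np.abs(flat - np.median(flat, axis=1, keepdims=True))
    zf = _z_scale_rows(folded).reshape(shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.maximum(_rhat_2d_batch(z), _rhat_2d_batch(zf))
    out[constant] = 1.0
    return out


def ess_bulk_batch(draws: np.ndarray) -> np.ndarray:
    """Bulk ESS for a (params, chains, draws) stack."""
    draws = np.asarray(draws, dtype=float)
    P, C, T = draws.shape
    if T < 4:
        raise ValueError("ESS requires at least 4 draws per chain")
    split = _split_chains_batch(draws)
    flat = split.reshape(P, -1)
    constant = np.ptp(flat, axis=1) < np.finfo(float).resolution
    z = _z_scale_rows(flat).reshape(split.shape)
    return _ess_from_z(z, constant)


def diagnose_batch(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank-normalized split R-hat and bulk ESS for a (params, chains, draws)
    stack, sharing one rank transform between the two diagnostics."""
    draws = np.asarray(draws, dtype=float)
    P, C, T = draws.shape
    if C < 2 or T < 4:
        raise ValueError("diagnostics require >= 2 chains and >= 4 draws per chain")
    split = _split_chains_batch(draws)
    flat = split.reshape(P, -1)
    constant = np.ptp(flat, axis=1) < np.finfo(float).resolution
    z = _z_scale_rows(flat).reshape(split.shape)
    folded = np.abs(flat - np.median(flat, axis=1, keepdims=True))
    zf = _z_scale_rows(folded).reshape(split.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.maximum(_rhat_2d_batch(z), _rhat_2d_batch(zf))
    rhat[constant] = 1.0
    return rhat, _ess_from_z(z, constant)


def _ess_from_z(z: np.ndarray, constant: np.ndarray) -> np.ndarray:
    P = z.shape[0]
    n_chain, n_draw = z.shape[1], z.shape[2]
    m = next_fast_len(2 * n_draw)
    centered = z - z.mean(axis=2, keepdims=True)
    fft = np.fft.rfft(centered, n=m, axis=2)
    fft *= np.conjugate(fft)
    acov = np.fft.irfft(fft, n=m, axis=2)[:, :, :n_draw] / n_draw

    mean_var = acov[:, :, 0].mean(axis=1) * n_draw / (n_draw - 1.0)
    var_plus = mean_var * (n_draw - 1.0) / n_draw + z.mean(axis=2).var(
        axis=1, ddof=1
    )
    mean_acov = acov.mean(axis=1)

    out = np.empty(P)
    for p in range(P):
        if constant[p]:
            out[p] = float(n_chain * n_draw)
            continue
        out[p] = _ess_from_acov(mean_acov[p], mean_var[p], var_plus[p], n_chain, n_draw)
    return out


def _ess_from_acov(
    mean_acov: np.ndarray, mean_var: float, var_plus: float, n_chain: int, n_draw: int
) -> float:
    rho_hat = np.zeros(n_draw)
    rho_even = 1.0
    rho_hat[0] = rho_even
    rho_odd = 1.0 - (mean_var - mean_acov[1]) / var_plus
    rho_hat[1] = rho_odd
    t = 1
    while t < (n_draw - 3) and (rho_even + rho_odd) > 0.0:
        rho_even = 1.0 - (mean_var - mean_acov[t + 1]) / var_plus
        rho_odd = 1.0 - (mean_var - mean_acov[t + 2]) / var_plus
        if (rho_even + rho_odd) >= 0:
            rho_hat[t + 1] = rho_even
            rho_hat[t + 2] = rho_odd
        t += 2
    max_t = t - 2
    if rho_even > 0:
        rho_hat[max_t + 1] = rho_even
    t = 1
    while t <= max_t - 2:
        if (rho_hat[t + 1] + rho_hat[t + 2]) > (rho_hat[t - 1] + rho_hat[t]):
            rho_hat[t + 1] = (rho_hat[t - 1] + rho_hat[t]) / 2.0
            rho_hat[t + 2] = rho_hat[t + 1]
        t += 2
    size = n_chain * n_draw
    tau_hat = -1.0 + 2.0 * rho_hat[: max_t + 1].sum() + rho_hat[max_t + 1]
    tau_hat = max(tau_hat, 1.0 / np.log10(size))
    return float(size / tau_hat)
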