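"""Independent test oracles, kept free of the code paths they check."""

import itertools

import numpy as np


def dft_matrix(n: int) -> np.ndarray:
    """Unitary DFT matrix (rows = frequency atoms)."""
    return np.fft.fft(np.eye(n), axis=1, norm="ortho")


def sparse_instance(seed: int, n: int = 16, n_samples: int = 8, k_sparse: int = 2):
    """Seeded 1D recovery instance: k-sparse spectrum observed at a random
    incoherence-optimized subset of time points.

    The time-sample subset is the best of 64 random candidates by peak
    point-spread sidelobe, the standard way variable-density CS masks are
    screened.  Returns (true spectrum, sample indices, zero-filled time signal).
    """
    rng = np.random.default_rng(seed)
    support = rng.choice(n, k_sparse, replace=False)
    coef = np.zeros(n, complex)
    coef[support] = (0.5 + rng.uniform(0, 1, k_sparse)) * np.exp(
        2j * np.pi * rng.uniform(0, 1, k_sparse)
    )
    best, best_sidelobe = None, np.inf
    for _ in range(64):
        cand = np.sort(rng.choice(n, n_samples, replace=False))
        ind = np.zeros(n)
        ind[cand] = 1.0
        sidelobe = np.sort(np.abs(np.fft.fft(ind)) / n_samples)[-2]
        if sidelobe < best_sidelobe:
            best_sidelobe, best = sidelobe, cand
    samples = best
    u = dft_matrix(n).conj().T @ coef
    y = np.zeros(n, complex)
    y[samples] = u[samples]
    return coef, samples, y


def exhaustive_l1(samples: np.ndarray, y: np.ndarray, n: int = 16, max_support: int = 3):
    """Minimum-l1 exact-fit solution by exhaustive search over supports.

    Enumerates every support up to ``max_support`` atoms, solves the least
    squares fit, keeps exact fits (residual < 1e-8 relative) and returns
    the one of minimal l1 norm as a dense length-n vector.
    """
    atoms = dft_matrix(n).conj().T[samples, :]
    ys = y[samples]
    best, best_l1 = None, np.inf
    for size in range(1, max_support + 1):
        for support in itertools.combinations(range(n), size):
            basis = atoms[:, support]
            c, *_ = np.linalg.lstsq(basis, ys, rcond=None)
            if np.linalg.norm(ys - basis @ c) < 1e-8 * np.linalg.norm(ys):
                l1 = np.abs(c).sum()
                if l1 < best_l1 - 1e-12:
                    best_l1 = l1
                    dense = np.zeros(n, complex)
                    dense[list(support)] = c
                    best = dense
    assert best is not None, "no exact-fit support found"
    return best


def focuss_toy_reconstruction(samples, y, n_foc, n=16, lam=0.0):
    """Run the package's FOCUSS engine on a 1D toy (1 x 1 x n grid) and
    return the recovered temporal spectrum."""
    import ktfmri as k
    from ktfmri.recon import ReconConfig, TemporalTransform, ktfocuss

    lines = np.zeros((1, n), bool)
    lines[0, samples] = True
    mask = k.SamplingMask("CUSTOM", lines, 1)
    data = np.where(lines[0], y.reshape(1, 1, n), 0.0 + 0.0j)
    ks = k.KSpaceSeries(data, mask=mask)
    res = ktfocuss(ks, ReconConfig.ft(lam=lam, n_foc=n_foc))
    phi = TemporalTransform.fourier(n)
    return phi.forward(res.series.frames).reshape(n)


def welch_t(x, y):
    """Direct-arithmetic Welch statistic and Welch-Satterthwaite df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    t = (x.mean() - y.mean()) / np.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df
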