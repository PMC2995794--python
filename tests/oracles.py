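"""Independent brute-force reference implementations used by the tests.

Everything here is written as a naive double loop straight from the
definitions so it stays independent of the vectorised/sparse code paths
it checks.
"""

from __future__ import annotations

import numpy as np


def naive_kc(chrom, pos, signal, grid, kernel):
    """Nadaraya–Watson smooth by explicit double loop, per chromosome."""
    out = np.zeros(grid.n_points)
    mass = np.zeros(grid.n_points)
    for i in range(grid.n_points):
        num = den = 0.0
        for j in range(len(pos)):
            if chrom[j] != grid.chrom[i]:
                continue
            d = pos[j] - grid.x[i]
            if abs(d) > kernel.support:
                continue
            w = np.exp(-(d ** 2) / (2.0 * kernel.sigma ** 2))
            num += w * signal[j]
            den += w
        mass[i] = den
        out[i] = num / den if den >= 1e-8 else 0.0
    return out, mass


def naive_pooled_sd(profiles, labels):
    labels = np.asarray(labels)
    g1 = profiles[labels == 1]
    g2 = profiles[labels == 2]
    n1, n2 = len(g1), len(g2)
    out = np.zeros(profiles.shape[1])
    for i in range(profiles.shape[1]):
        v1 = np.sum((g1[:, i] - g1[:, i].mean()) ** 2) / (n1 - 1)
        v2 = np.sum((g2[:, i] - g2[:, i].mean()) ** 2) / (n2 - 1)
        out[i] = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    return out


def naive_snr(profiles, labels):
    """SNR from the definitions, including the 95th-percentile f."""
    labels = np.asarray(labels)
    sd = naive_pooled_sd(profiles, labels)
    f = np.quantile(sd, 0.95)
    mu1 = profiles[labels == 1].mean(axis=0)
    mu2 = profiles[labels == 2].mean(axis=0)
    return (mu1 - mu2) / (sd + f), f


def enumerate_value_permutation_maxima(chrom, pos, summed, grid, kernel,
                                       n_perms, seed):
    """Re-enumerate the seeded value shuffles and smooth them naively."""
    max_g = np.empty(n_perms)
    max_l = np.empty(n_perms)
    children = np.random.SeedSequence(seed).spawn(n_perms)
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        perm = rng.permutation(summed)
        g = np.maximum(perm, 0.0)
        l = np.maximum(-perm, 0.0)
        kg, _ = naive_kc(chrom, pos, g, grid, kernel)
        kl, _ = naive_kc(chrom, pos, l, grid, kernel)
        max_g[k] = max(kg.max(), 0.0)
        max_l[k] = max(kl.max(), 0.0)
    return max_g, max_l


def enumerate_label_permutation_threshold(profiles, labels, fdr_target,
                                          n_perms, seed):
    """Re-enumerate the seeded label shuffles and scan candidate
    thresholds by explicit counting."""
    labels = np.asarray(labels)
    snr_obs, _ = naive_snr(profiles, labels)
    abs_obs = np.abs(snr_obs)
    null = []
    children = np.random.SeedSequence(seed).spawn(n_perms)
    for child in children:
        rng = np.random.default_rng(child)
        perm = rng.permutation(labels)
        s, _ = naive_snr(profiles, perm)
        null.append(np.abs(s))
    null = np.asarray(null)
    best = np.inf
    for t in np.unique(abs_obs):
        obs_count = int(np.sum(abs_obs >= t))
        null_mean = float(np.mean(np.sum(null >= t, axis=1)))
        fdr_hat = min(1.0, null_mean / obs_count)
        if fdr_hat <= fdr_target and t < best:
            best = t
    return best
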