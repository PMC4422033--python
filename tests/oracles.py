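"""Independent oracles for the test suite.

These deliberately avoid the package's channel-update kernels: the
Gillespie simulator is an exact continuous-time realisation of the same
Markov schemes, and the master-equation matrices are built directly
from the transition diagram, so both can cross-check the fixed-step
channel-state-tracking implementation.
"""

import numpy as np

from srneuron.channel_kinetics import rate_functions


def k_rate_matrix(v: float) -> np.ndarray:
    """Generator matrix Q (5x5) of the K-channel occupancy chain at clamp.

    State i = number of open n-particles; i -> i+1 at (4-i) alpha_n,
    i -> i-1 at i beta_n.  Row-sums are zero.
    """
    r = rate_functions(v)
    q = np.zeros((5, 5))
    for i in range(5):
        if i < 4:
            q[i, i + 1] = (4 - i) * r.alpha_n
        if i > 0:
            q[i, i - 1] = i * r.beta_n
        q[i, i] = -q[i].sum()
    return q


def na_rate_matrix(v: float) -> np.ndarray:
    """Generator matrix Q (8x8) of the Na-channel occupancy chain.

    State index s = 2*i + j with i open m-particles (0..3) and
    h-particle state j (0 closed, 1 open).
    """
    r = rate_functions(v)
    q = np.zeros((8, 8))
    for i in range(4):
        for j in range(2):
            s = 2 * i + j
            if i < 3:
                q[s, 2 * (i + 1) + j] = (3 - i) * r.alpha_m
            if i > 0:
                q[s, 2 * (i - 1) + j] = i * r.beta_m
            q[s, 2 * i + (1 - j)] = r.alpha_h if j == 0 else r.beta_h
            q[s, s] = -q[s].sum() + q[s, s]
    return q


def gillespie_k(n_channels: int, v: float, t_total: float, seed: int,
                t_burn: float = 50.0, n_blocks: int = 20):
    """Exact SSA of the K ensemble under voltage clamp.

    Returns per-block time averages of the open-channel count over
    ``n_blocks`` equal blocks of the post-burn-in interval (ms), from
    which mean and standard error follow.
    """
    rng = np.random.default_rng(seed)
    r = rate_functions(v)
    counts = np.zeros(5, dtype=np.int64)
    counts[0] = n_channels
    t = 0.0
    block_len = (t_total - t_burn) / n_blocks
    block_sums = np.zeros(n_blocks)

    def accumulate(t0, t1, open_count):
        """Add open_count weighted by overlap of [t0, t1] with each block."""
        if t1 <= t_burn:
            return
        lo = max(t0, t_burn)
        b0 = int((lo - t_burn) // block_len)
        b1 = int(min((t1 - t_burn) // block_len, n_blocks - 1))
        for b in range(b0, b1 + 1):
            a = max(lo, t_burn + b * block_len)
            z = min(t1, t_burn + (b + 1) * block_len)
            if z > a:
                block_sums[b] += (z - a) * open_count

    while t < t_total:
        up = np.array([(4 - i) * r.alpha_n * counts[i] for i in range(5)])
        dn = np.array([i * r.beta_n * counts[i] for i in range(5)])
        total = up.sum() + dn.sum()
        dt = rng.exponential(1.0 / total)
        accumulate(t, min(t + dt, t_total), counts[4])
        t += dt
        if t >= t_total:
            break
        u = rng.uniform(0.0, total)
        cum = 0.0
        for i in range(5):
            cum += up[i]
            if u < cum:
                counts[i] -= 1
                counts[i + 1] += 1
                break
        else:
            for i in range(5):
                cum += dn[i]
                if u < cum:
                    counts[i] -= 1
                    counts[i - 1] += 1
                    break
    return block_sums / block_len
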