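"""Independent step-by-step transcription of the restructuring procedure.

Deliberately written with plain Python loops and lists, separate from the
vectorized implementation, so the two can cross-check each other
elementwise.  The steps (documented in ``stockhab.lfq.restructure``):
moving-average ratio minus one, positive normalisation by the column mean
of positives, isolated-peak damping by 2**(adjacent zero-count bins), and
a -0.01-per-bin cumulative penalty on runs of zero-count bins.
"""

import numpy as np


def restructure_oracle(counts: np.ndarray, ma_window: int) -> np.ndarray:
    n_bins, n_samples = counts.shape
    half = ma_window // 2
    out = np.zeros((n_bins, n_samples))
    for j in range(n_samples):
        col = [float(c) for c in counts[:, j]]
        # 1. centred moving average over available neighbours
        ma = []
        for i in range(n_bins):
            window = [col[t] for t in range(i - half, i + half + 1) if 0 <= t < n_bins]
            ma.append(sum(window) / len(window))
        # 2. ratio minus one (zero where the window is empty)
        r = [col[i] / ma[i] - 1.0 if ma[i] > 0 else 0.0 for i in range(n_bins)]
        # 3. divide positives by the mean positive value
        positives = [v for v in r if v > 0]
        if positives:
            mean_pos = sum(positives) / len(positives)
            r = [v / mean_pos if v > 0 else v for v in r]
        # 4. damp isolated peaks by 2**(number of zero-count neighbours)
        for i in range(n_bins):
            if r[i] > 0:
                nz = 0
                if i - 1 >= 0 and col[i - 1] == 0:
                    nz += 1
                if i + 1 < n_bins and col[i + 1] == 0:
                    nz += 1
                r[i] = r[i] / (2**nz)
        # 5. cumulative penalty along runs of zero-count bins
        run = 0
        for i in range(n_bins):
            if col[i] == 0:
                run += 1
                r[i] = -0.01 * run
            else:
                run = 0
        out[:, j] = r
    return out
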