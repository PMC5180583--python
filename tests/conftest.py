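import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_local_entropy(channel, se, excl=None):
    """Independent per-pixel oracle: explicit histogram at every pixel.

    Reflect (symmetric) padding, excluded pixels dropped from histograms,
    excluded or empty-neighborhood centers get 0 / invalid.
    """
    channel = np.asarray(channel)
    h, w = channel.shape
    r = se.radius
    if excl is None:
        excl = np.zeros((h, w), dtype=bool)
    pad_ch = np.pad(channel, r, mode="symmetric")
    pad_ok = np.pad(~np.asarray(excl, dtype=bool), r, mode="symmetric")
    H = np.zeros((h, w))
    valid = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            vals = [
                pad_ch[i + r + di, j + r + dj]
                for di, dj in se.offsets
                if pad_ok[i + r + di, j + r + dj]
            ]
            if excl[i, j] or not vals:
                continue
            cnt = np.bincount(np.asarray(vals, dtype=np.int64), minlength=256)
            p = cnt[cnt > 0] / cnt.sum()
            H[i, j] = -(p * np.log2(p)).sum()
            valid[i, j] = True
    return H, valid
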