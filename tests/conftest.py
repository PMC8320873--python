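import numpy as np
import pytest

from lisaq import LisaConfig, PhantomSpec, brain_like_phantom, make_phantom


def naive_local_moran(x: np.ndarray, config: LisaConfig | None = None) -> np.ndarray:
    """Independent triple-loop local Moran oracle with replicate padding.

    Deliberately scalar and index-based so it shares no code path with the
    vectorized implementation.
    """
    cfg = config or LisaConfig()
    x = np.asarray(x, dtype=float)
    h, w = x.shape
    kr, kc = cfg.kernel_shape
    out = np.empty((h, w))
    if cfg.stat_scope == "image":
        xbar = x.mean()
        s2 = float(np.mean((x - xbar) ** 2))
        if s2 == 0.0:
            return np.ones((h, w))
    for i in range(h):
        for j in range(w):
            window, neigh = [], []
            for di in range(-(kr // 2), kr // 2 + 1):
                for dj in range(-(kc // 2), kc // 2 + 1):
                    v = x[min(max(i + di, 0), h - 1), min(max(j + dj, 0), w - 1)]
                    window.append(v)
                    if di or dj:
                        neigh.append(v)
            neigh = np.asarray(neigh)
            if cfg.stat_scope == "image":
                out[i, j] = (x[i, j] - xbar) / s2 * float(np.mean(neigh - xbar))
            else:
                if neigh.min() == neigh.max():
                    out[i, j] = 1.0 if x[i, j] == neigh[0] else -1.0
                    continue
                m = float(np.mean(window)) if cfg.mean_includes_center else float(np.mean(neigh))
                s2_local = float(np.mean((neigh - m) ** 2))
                out[i, j] = (x[i, j] - m) / s2_local * float(np.mean(neigh - m))
    return out


@pytest.fixture
def naive_moran():
    return naive_local_moran


@pytest.fixture(scope="session")
def uniform64():
    return make_phantom(PhantomSpec(kind="uniform", height=64, width=64, high=200.0))


@pytest.fixture(scope="session")
def checkerboard64():
    return make_phantom(PhantomSpec(kind="checkerboard", height=64, width=64, low=0.0, high=1.0))


@pytest.fixture(scope="session")
def brain64():
    return brain_like_phantom(64, 64, seed=1)


@pytest.fixture(scope="session")
def window_config():
    return LisaConfig(stat_scope="window")
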