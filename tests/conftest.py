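import numpy as np
import pytest

import physcap as pc


@pytest.fixture(scope="session")
def qs_recording():
    return pc.generate_qs_recording(seed=101)


@pytest.fixture(scope="session")
def walk_recording():
    return pc.generate_walk_recording(seed=202)


@pytest.fixture(scope="session")
def cst_recording():
    return pc.generate_cst_recording(seed=303, sts_dur_sd=0.08)


@pytest.fixture(scope="session")
def qs_loadings():
    return pc.load_loading_matrix("qs")


def align_columns(L_est: np.ndarray, L_true: np.ndarray) -> np.ndarray:
    """Permute and sign-flip estimated factor columns to best match the truth
    (greedy on absolute congruence)."""
    L_est = np.asarray(L_est, float).copy()
    L_true = np.asarray(L_true, float)
    k = L_true.shape[1]
    C = np.abs(L_est.T @ L_true)
    order, used = [], set()
    for j in range(k):
        cands = np.argsort(C[:, j])[::-1]
        pick = next(c for c in cands if c not in used)
        used.add(pick)
        order.append(pick)
    out = L_est[:, order]
    for j in range(k):
        if out[:, j] @ L_true[:, j] < 0:
            out[:, j] = -out[:, j]
    return out


def congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence coefficient of two loading vectors."""
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))
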