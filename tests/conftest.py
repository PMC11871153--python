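import math

import numpy as np
import pytest

from leadgraph import Cohort, WaveformRecord


def random_cohort(n_records=10, L=4, T=50, seed=0, labels=True, n_classes=2) -> Cohort:
    """Unstructured random cohort for contract tests."""
    rng = np.random.default_rng(seed)
    lead_names = tuple(f"L{i}" for i in range(L))
    records = []
    for k in range(n_records):
        records.append(
            WaveformRecord(
                signal=rng.normal(size=(L, T)),
                lead_names=lead_names,
                sampling_rate=100.0,
                record_id=f"r{k:03d}",
                labels=int(rng.integers(n_classes)) if labels else None,
            )
        )
    names = tuple(f"class{c}" for c in range(n_classes)) if labels else None
    return Cohort(records=records, class_names=names)


def pearson_brute(x, y) -> float:
    """Independent brute-force Pearson correlation (pure-Python arithmetic)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    if dx == 0.0 or dy == 0.0:
        return 0.0
    return num / (dx * dy)


def graph_brute(cohort: Cohort) -> np.ndarray:
    """Brute-force cohort-average pairwise correlation matrix, zero diagonal."""
    L = cohort.n_leads
    A = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            vals = []
            for rec in cohort.records:
                xi = list(rec.signal[i])
                xj = list(rec.signal[j])
                if max(xi) == min(xi) or max(xj) == min(xj):
                    continue  # constant lead: excluded from this pair
                vals.append(pearson_brute(xi, xj))
            A[i, j] = sum(vals) / len(vals) if vals else 0.0
    return A


def macro_f1_brute(y_true, y_pred, n_classes=None, multilabel=False) -> float:
    """Hand-coded confusion-matrix macro-F1 oracle."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if multilabel:
        f1s = []
        for c in range(y_true.shape[1]):
            f1s.append(_binary_f1(y_true[:, c], y_pred[:, c]))
        return float(np.mean(f1s))
    K = n_classes or int(max(y_true.max(), y_pred.max())) + 1
    f1s = []
    for c in range(K):
        f1s.append(_binary_f1(y_true == c, y_pred == c))
    return float(np.mean(f1s))


def _binary_f1(t, p) -> float:
    tp = int(np.sum(t & (p == 1))) if t.dtype == bool else int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum(~t & (p == 1))) if t.dtype == bool else int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum(t & (p == 0))) if t.dtype == bool else int(np.sum((t == 1) & (p == 0)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort():
    return random_cohort(n_records=6, L=3, T=40, seed=7)
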