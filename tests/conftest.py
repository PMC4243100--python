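import numpy as np
import pytest

from resi import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_ds():
    """A small valid 6x4 dataset with a 2/4 class split."""
    rng = np.random.default_rng(7)
    values = rng.normal(size=(6, 4))
    return ExpressionDataset(
        values=values,
        labels=np.array(["tumor", "tumor", "normal", "normal", "normal", "normal"]),
        feature_ids=[f"g{j}" for j in range(4)],
        instance_ids=[f"s{i}" for i in range(6)],
    )


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive; used to cross-check the
# vectorised production code)
# ---------------------------------------------------------------------------

def purity_oracle(values, labels, k):
    """O(n^2) neighbourhood purity by explicit enumeration."""
    n = len(values)
    out = []
    for u in range(n):
        ranked = sorted(
            (abs(values[v] - values[u]), v) for v in range(n) if v != u
        )
        neighbours = [v for _, v in ranked[:k]]
        out.append(sum(labels[v] == labels[u] for v in neighbours) / k)
    return out


def blur_oracle(values, labels, k, mu):
    """Blur set by exact rational comparison count/k <= mu."""
    from fractions import Fraction

    n = len(values)
    mask = []
    for u in range(n):
        ranked = sorted(
            (abs(values[v] - values[u]), v) for v in range(n) if v != u
        )
        count = sum(labels[v] == labels[u] for _, v in ranked[:k])
        mask.append(Fraction(count, k) <= Fraction(mu))
    return mask


def remi_oracle(blur_p, blur_q):
    """Literal set-counting redundancy measure."""
    sp = {u for u, b in enumerate(blur_p) if b}
    sq = {u for u, b in enumerate(blur_q) if b}
    if not sp:
        return 0.0
    return len(sp & sq) / len(sp)
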