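import numpy as np
import pandas as pd
import pytest

from wildg.pedigree import Pedigree, from_frame


def random_pedigree_frame(rng: np.random.Generator, n: int, n_founders: int) -> pd.DataFrame:
    """Random valid pedigree: founders first, then offspring of earlier
    individuals (possibly with one unknown parent)."""
    rows = []
    for i in range(n_founders):
        rows.append((f"i{i}", "NA", "NA", 1))
    for i in range(n_founders, n):
        lo = max(0, i - 5 * n_founders)
        s = int(rng.integers(lo, i))
        d = int(rng.integers(lo, i))
        while d == s:
            d = int(rng.integers(lo, i))
        sire = f"i{s}" if rng.random() > 0.1 else "NA"
        dam = f"i{d}" if rng.random() > 0.1 else "NA"
        rows.append((f"i{i}", sire, dam, 2 + i // max(1, n_founders)))
    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "cohort"])
    df["population"] = "test"
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def trio() -> Pedigree:
    return from_frame(
        pd.DataFrame(
            {
                "id": ["A", "B", "C"],
                "sire": ["NA", "NA", "A"],
                "dam": ["NA", "NA", "B"],
                "cohort": [1, 1, 2],
                "population": ["x"] * 3,
            }
        )
    )


def make_random_pedigree(seed: int, n: int = 120, n_founders: int = 30) -> Pedigree:
    rng = np.random.default_rng(seed)
    return from_frame(random_pedigree_frame(rng, n, n_founders))


def random_psd(rng, n, scale=1.0):
    A = rng.standard_normal((n, n))
    return scale * (A @ A.T) / n + 1e-6 * np.eye(n)
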