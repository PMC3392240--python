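import numpy as np
import pytest

from melanosim.core import Cell, CellType, Dish


@pytest.fixture
def dish():
    return Dish()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cell(cid, x, y, ctype=CellType.MELANOCYTE, **kw):
    return Cell(cid, ctype, float(x), float(y), **kw)


@pytest.fixture
def random_cells(rng):
    """A reproducible scattering of mixed-type cells over the dish."""
    def _make(n, mel_fraction=0.3, dish=None, seed=None):
        d = dish or Dish()
        local = np.random.default_rng(seed) if seed is not None else rng
        xy = local.uniform(10.0, d.side - 10.0, size=(n, 2))
        types = np.where(local.uniform(size=n) < mel_fraction,
                         CellType.MELANOCYTE, CellType.TA_KERATINOCYTE)
        return [Cell(i, CellType(int(t)), float(p[0]), float(p[1]))
                for i, (t, p) in enumerate(zip(types, xy))]
    return _make
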