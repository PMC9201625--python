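import numpy as np
import pytest

from onet import nn


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(autouse=True)
def _seed_param_init():
    # every test starts from the same parameter-initialisation stream
    nn.manual_seed(0)


def finite_difference_gradcheck(fn, *arrays, eps=1e-6, tol=1e-4, rng=None):
    """Compare autodiff gradients of ``fn`` against central differences.

    ``fn`` maps Tensors to one Tensor; ``arrays`` are the float inputs to
    perturb.  Output is projected onto a fixed random direction.
    """
    rng = rng or np.random.default_rng(42)
    ts = [nn.Tensor(np.array(a, dtype=float), requires_grad=True) for a in arrays]
    out = fn(*ts)
    g = rng.normal(size=out.data.shape)
    out.backward(g)
    for t in ts:
        num = np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        nflat = num.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            fp = np.array(fn(*ts).data)
            flat[i] = orig - eps
            fm = np.array(fn(*ts).data)
            flat[i] = orig
            nflat[i] = ((fp - fm) * g).sum() / (2 * eps)
        err = np.abs(num - t.grad).max()
        assert err < tol, f"gradient mismatch {err:.2e} (tol {tol})"


@pytest.fixture
def gradcheck():
    return finite_difference_gradcheck
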