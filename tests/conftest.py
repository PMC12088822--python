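import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def _relerr(ga: np.ndarray, gn: np.ndarray) -> float:
    na, nn = np.linalg.norm(ga), np.linalg.norm(gn)
    return float(np.linalg.norm(ga - gn) / max(na + nn, 1e-30))


def finite_difference_check(loss_fn, params, eps: float = 1e-6) -> float:
    """Max relative error between analytic and central-difference gradients.

    ``loss_fn()`` returns (loss, grads) with grads aligned to ``params``;
    parameters are perturbed in place.
    """
    _, grads = loss_fn()
    errs = []
    for p, g in zip(params, grads):
        gn = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = p[i]
            p[i] = orig + eps
            lp, _ = loss_fn()
            p[i] = orig - eps
            lm, _ = loss_fn()
            p[i] = orig
            gn[i] = (lp - lm) / (2 * eps)
        errs.append(_relerr(np.asarray(g), gn))
    return max(errs)


@pytest.fixture
def gradcheck():
    return finite_difference_check
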