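import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import integrate, stats

import pathrates as pr

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=list(HealthCheck),
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def yeast_tree():
    return pr.yeast_fixture_tree()


@pytest.fixture(scope="session")
def toy_tree():
    return pr.parse_newick("((A:1,B:1):1,C:2);")


def random_ultrametric_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random ultrametric topology by sequential pairwise coalescence."""
    nodes = [(f"t{i}", 0.0) for i in range(n_tips)]
    while len(nodes) > 1:
        h = max(height for _, height in nodes) + rng.uniform(0.1, 1.0)
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = (f"({na}:{h - ha:.12f},{nb}:{h - hb:.12f})", h)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0][0] + ";"


def quadrature_marginal_loglik(y, Vprime, alpha, beta) -> float:
    """Independent oracle: one-dimensional adaptive quadrature of the
    Gaussian likelihood against the inverse-gamma rate density."""
    y = np.asarray(y, dtype=float)
    m = y.size
    Vp = np.asarray(Vprime, dtype=float)
    q = float(y @ np.linalg.solve(Vp, y))
    logdet = float(np.linalg.slogdet(Vp)[1])

    def integrand(s):
        log_gauss = -0.5 * (m * np.log(2 * np.pi * s) + logdet + q / s)
        return np.exp(log_gauss) * stats.invgamma.pdf(s, a=alpha, scale=beta)

    val, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-14, epsrel=1e-12,
                            limit=400)
    return float(np.log(val))
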