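import numpy as np
import pytest

from fbdmsc.trees import TimeTree, TimeTreeNode, parse_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20210706)


@pytest.fixture
def ultrametric3():
    return parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4():
    return parse_tree("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture
def sa_tree():
    """2 extant + 1 fossil, fossil as a sampled ancestor above A."""
    f = TimeTreeNode(label="F1", age=0.5, is_sample=True)
    a = TimeTreeNode(label="A", age=0.0, is_sample=True)
    f.add_child(a)
    b = TimeTreeNode(label="B", age=0.0, is_sample=True)
    root = TimeTreeNode(age=1.0, children=[f, b])
    return TimeTree(root, origin_age=1.5)


@pytest.fixture
def fossil_tip_tree():
    """2 extant + 1 fossil tip sister to A."""
    f = TimeTreeNode(label="F1", age=0.5, is_sample=True)
    a = TimeTreeNode(label="A", age=0.0, is_sample=True)
    b = TimeTreeNode(label="B", age=0.0, is_sample=True)
    inner = TimeTreeNode(age=0.8, children=[a, f])
    root = TimeTreeNode(age=1.2, children=[inner, b])
    return TimeTree(root, origin_age=1.5)


def sample_config_state(lam=1.0, mu=0.3, psi=0.8, rho=1.0, x0=1.5,
                        survival=False):
    """Prior-only model state over the 2-extant + 1-fossil configuration."""
    from fbdmsc.priors import Fixed
    from fbdmsc.state import ModelState

    f = TimeTreeNode(label="F1", age=0.5, is_sample=True)
    t1 = TimeTreeNode(label="T1", age=0.0, is_sample=True)
    t2 = TimeTreeNode(label="T2", age=0.0, is_sample=True)
    inner = TimeTreeNode(age=0.9, children=[f, t1])
    root = TimeTreeNode(age=1.2, children=[inner, t2])
    params = {"lambda": lam, "mu": mu, "psi": psi, "rho": rho,
              "origin_age": x0}
    return ModelState(TimeTree(root), params,
                      {k: Fixed(v) for k, v in params.items()},
                      mode="fbd-msc", fbd_survival=survival)
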