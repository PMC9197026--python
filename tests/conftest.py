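import numpy as np
import pytest

from shmindel.core import (
    IndelModel,
    LengthDistribution,
    MuPrior,
    NucleotideSequence,
    TemplateSet,
)
from shmindel.simulate import benchmark_model, generate_repertoire, random_templates


def make_prior(f=0.1, bin_width=0.01, decay=0.05):
    """A coarse-binned, exponentially decaying age prior for fast tests."""
    n = int(round(1 / bin_width))
    centers = (np.arange(n) + 0.5) * bin_width
    dens = np.exp(-centers / decay)
    dens /= dens.sum() * bin_width
    return MuPrior(f=f, density=dens, bin_width=bin_width)


@pytest.fixture(scope="session")
def small_model():
    """Tiny model (theta_max = 3) suitable for brute-force enumeration."""
    return IndelModel(
        prior=make_prior(),
        beta_del=0.02,
        beta_ins=0.03,
        len_del=LengthDistribution([0.5, 0.3, 0.2]),
        len_ins=LengthDistribution([0.6, 0.3, 0.1]),
    )


@pytest.fixture(scope="session")
def bench_templates():
    return random_templates(4, 120, seed=101)


@pytest.fixture(scope="session")
def bench_model():
    """Benchmark generative conditions at reduced indel-length cutoff for speed."""
    return benchmark_model(theta_max=15, length_scale=6.0, bin_width=0.002)


@pytest.fixture(scope="session")
def bench_rep(bench_templates, bench_model):
    """A medium synthetic repertoire reused across statistics tests."""
    return generate_repertoire(bench_templates, bench_model, 400, seed=2024)


def seq(s, name="s"):
    return NucleotideSequence(id=name, seq=s)


@pytest.fixture
def seqs():
    return seq
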