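import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from shmindel.core import MutationEvent, MutationScenario, NucleotideSequence
from shmindel.simulate import benchmark_model, generate_repertoire, random_templates
from shmindel import stats as st


@pytest.fixture(scope="module")
def truth_annots(bench_rep):
    return st.from_truth(bench_rep)


def make_annot(template, events, read_id="r"):
    sc = MutationScenario(template.id, 0.05, events)
    read = NucleotideSequence(read_id, sc.apply(template))
    return st.AnnotatedRead(read=read, template=template, scenario=sc)


@pytest.fixture(scope="module")
def tpl():
    return random_templates(1, 120, seed=404).templates[0]


class TestIndelCounts:
    def test_indel_free_repertoire(self, tpl):
        annots = [make_annot(tpl, [], f"r{i}") for i in range(10)]
        df, means = st.indel_count_distribution(annots)
        assert df.loc[df.n == 0, "all"].iloc[0] == 1.0
        assert means["all"] == 0.0

    def test_poisson_mean_recovery(self, tpl):
        rng = np.random.default_rng(3)
        n = 20000
        counts = rng.poisson(0.3, size=n)
        annots = []
        for i, c in enumerate(counts):
            events = [MutationEvent("del", 2 * k, 1) for k in range(c)]
            annots.append(make_annot(tpl, events, f"r{i}"))
        _, means = st.indel_count_distribution(annots)
        assert abs(means["del"] - 0.3) < 3 * np.sqrt(0.3 / n)

    def test_generative_counts_are_super_poissonian(self, truth_annots):
        """Age variability across sequences makes indel counts overdispersed."""
        counts = np.array(
            [a.scenario.n_del + a.scenario.n_ins for a in truth_annots]
        )
        assert counts.var() > counts.mean()


class TestSHMConditional:
    def test_increasing_with_indel_count(self, truth_annots):
        df = st.shm_conditional_on_indels(truth_annots)
        m0 = df.loc[df.n_indels == 0, "mean_shm"].iloc[0]
        m1 = df.loc[df.n_indels >= 1, "mean_shm"].iloc[0]
        assert m1 > m0


class TestFlankOverlap:
    def test_duplication_has_full_5p_overlap(self, tpl):
        j, ell = 40, 5
        dup = tpl.seq[j - ell : j]
        a = make_annot(tpl, [MutationEvent("ins", j, ell, inserted_seq=dup)])
        df = st.insertion_flank_overlap([a])
        assert len(df) == 1
        assert df.overlap.iloc[0] == 1.0
        assert df.overlap_5p.iloc[0] == 1.0

    def test_mismatching_insert_scores_zero(self, tpl):
        j, ell = 40, 4
        comp = {"A": "C", "C": "A", "G": "T", "T": "G"}
        flank5 = tpl.seq[j - ell : j]
        flank3 = tpl.seq[j : j + ell]
        ins = "".join(comp[b] for b in flank5)
        if any(x == y for x, y in zip(ins, flank3)):
            ins = "".join(comp[max(set("ACGT") - {x, y}, key="ACGT".index)]
                          for x, y in zip(flank5, flank3))
        a = make_annot(tpl, [MutationEvent("ins", j, ell, inserted_seq=ins)])
        df = st.insertion_flank_overlap([a])
        assert df.overlap.iloc[0] == 0.0

    def test_boundary_insertions_skipped(self, tpl):
        a = make_annot(tpl, [MutationEvent("ins", 1, 5, inserted_seq="ACGTA")])
        df = st.insertion_flank_overlap([a])
        assert len(df) == 0
        assert df.attrs["n_skipped"] == 1

    def test_random_inserts_match_randomized_null(self, bench_rep):
        """The simulator has no duplication mechanism: overlap ~ randomized null."""
        annots = st.from_truth(bench_rep)
        obs = st.insertion_flank_overlap(annots)
        null = pd.concat(
            [st.insertion_flank_overlap(annots, randomize=True, rng=k) for k in range(6)]
        )
        assert len(obs) >= 20
        se = np.sqrt(obs.overlap.var() / len(obs) + null.overlap.var() / len(null))
        assert abs(obs.overlap.mean() - null.overlap.mean()) < 3 * se
        # and the max over two flanks exceeds the single-flank expectation of 1/4
        assert null.overlap.mean() > 0.25

    def test_deletion_overlap_duplication_and_null(self, tpl):
        j, ell = 60, 4
        a = make_annot(tpl, [MutationEvent("del", j, ell)])
        df = st.deletion_flank_overlap([a])
        assert len(df) == 1
        expected5 = np.mean(
            [x == y for x, y in zip(tpl.seq[j : j + ell], tpl.seq[j - ell : j])]
        )
        expected3 = np.mean(
            [x == y for x, y in zip(tpl.seq[j : j + ell], tpl.seq[j + ell : j + 2 * ell])]
        )
        assert df.overlap.iloc[0] == pytest.approx(max(expected5, expected3))


class TestPairDistances:
    def test_distance_definition(self, tpl):
        a = make_annot(tpl, [MutationEvent("del", 5, 5), MutationEvent("del", 15, 2)])
        # first deletion ends (exclusive) at 10, second starts at 15 -> 5 bp between
        assert st.deletion_pair_distances([a]).tolist() == [5]

    def test_filters_reads_with_insertions(self, tpl):
        a = make_annot(
            tpl,
            [
                MutationEvent("del", 5, 2),
                MutationEvent("del", 20, 2),
                MutationEvent("ins", 50, 1, inserted_seq="A"),
            ],
        )
        assert len(st.deletion_pair_distances([a])) == 0


class TestPositionalProfiles:
    def test_uniform_model_profiles_are_flat(self, truth_annots):
        """Events placed uniformly along the template give flat profiles."""
        df, _ = st.positional_profiles(truth_annots)
        ok = ~df.masked
        counts = (df.point_rate[ok] * df.coverage[ok]).round().astype(int)
        _, p = sps.chisquare(counts)
        assert p > 1e-3

    def test_identical_profiles_correlate_perfectly(self, tpl):
        annots = []
        rng = np.random.default_rng(8)
        for i in range(30):
            pos = int(rng.integers(5, 100))
            events = [
                MutationEvent("point", pos, 1, new_base="A" if tpl.seq[pos] != "A" else "C"),
                MutationEvent("del", pos, 1),
            ]
            annots.append(make_annot(tpl, events, f"r{i}"))
        _, corr = st.positional_profiles(annots)
        r = corr.loc[(corr.profile_x == "point") & (corr.profile_y == "del"), "r"].iloc[0]
        assert r == pytest.approx(1.0)

    def test_low_coverage_positions_masked(self, tpl):
        short = NucleotideSequence("short", tpl.seq[:50])
        annots = [make_annot(short, [], f"s{i}") for i in range(99)]
        annots.append(make_annot(tpl, [], "long"))
        df, _ = st.positional_profiles(annots, min_coverage_frac=0.02)
        assert not df.masked[df.position < 50].any()
        assert df.masked[df.position >= 50].all()  # 1/100 reads < 2%


class TestColocalization:
    def test_independent_placement_ratio_near_one(self, truth_annots):
        df = st.colocalization_null(truth_annots, seed=1, n_perm=10)
        ok = df.dropna()
        near = ok[ok.distance <= 10]
        assert len(near) >= 5
        assert np.nanmean(np.abs(near.ratio - 1.0)) < 0.5

    def test_constructed_colocalization_detected(self, tpl):
        """Indels placed exactly on each read's own SHM sites inflate the ratio at 0."""
        rng = np.random.default_rng(9)
        annots = []
        for i in range(40):
            positions = sorted(rng.choice(np.arange(5, 110), size=3, replace=False))
            events = []
            for p in positions:
                p = int(p)
                events.append(MutationEvent("point", p, 1,
                                            new_base="A" if tpl.seq[p] != "A" else "C"))
            events.append(MutationEvent("del", int(positions[0]), 1))
            annots.append(make_annot(tpl, events, f"r{i}"))
        df = st.colocalization_null(annots, seed=2, n_perm=20)
        assert df.loc[df.distance == 0, "ratio"].iloc[0] > 1.5


class TestQualityFilter:
    def test_coverage_threshold(self):
        t_long = random_templates(1, 250, seed=5).templates[0]
        t_short = NucleotideSequence("short", t_long.seq[:150])
        kept_read = make_annot(t_long, [])
        dropped_read = make_annot(t_short, [])
        kept, n_dropped = st.quality_filter([kept_read, dropped_read], min_coverage=200)
        assert len(kept) == 1 and n_dropped == 1
        assert kept[0].read.id == kept_read.read.id

    def test_filter_preserves_short_length_spectrum(self):
        """Dropping low-coverage reads barely alters the deletion-length law."""
        templates = random_templates(1, 260, seed=6)
        model = benchmark_model(theta_max=40, beta_del=0.1, beta_ins=0.0,
                                length_scale=15.0, bin_width=0.002)
        rep = generate_repertoire(templates, model, 400, seed=7)
        annots = st.from_truth(rep)
        kept, n_dropped = st.quality_filter(annots, min_coverage=200)
        assert 0 < n_dropped < len(annots)
        all_lengths = [e.length for a in annots for e in a.scenario.events if e.kind == "del"]
        kept_lengths = [e.length for a in kept for e in a.scenario.events if e.kind == "del"]
        a = np.array([l for l in all_lengths if l <= 20])
        k = np.array([l for l in kept_lengths if l <= 20])
        _, p = sps.ks_2samp(a, k)
        assert p > 1e-3


class TestLengthScaleFit:
    def test_recovers_geometric_scale_exactly(self):
        from shmindel.core import LengthDistribution

        probs = LengthDistribution.geometric(15.0, 30).probs
        assert st.fit_exponential_length_scale(probs) == pytest.approx(15.0, rel=1e-9)

    def test_rejects_non_decaying(self):
        with pytest.raises(ValueError):
            st.fit_exponential_length_scale(np.full(10, 0.1))
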