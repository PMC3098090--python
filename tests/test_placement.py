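import numpy as np
import pytest

from phyloplace import simeval
from phyloplace.confidence import likelihood_weight_ratios
from phyloplace.placefile import PlacementRun, write_place
from phyloplace.placement import (
    BaseballParams, Placer, PlacementCandidate, UnplaceableReadError,
    find_friends, mask_query,
)
from phyloplace.reference import ReferenceAlignment, attachment_loglike_grid

from .conftest import make_fragment_read
from .oracles import placement_loglike


class TestMasking:
    def test_all_gap_read_is_unplaceable(self, small_fixture):
        n = small_fixture["aln"].n_columns
        with pytest.raises(UnplaceableReadError):
            mask_query("q", "-" * n, "nt", n)

    def test_mask_counts_informative_columns(self):
        read = mask_query("q", "AC--GN" + "-" * 194, "nt", 200)
        assert read.mask.tolist() == [0, 1, 4]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            mask_query("q", "ACGT", "nt", 10)

    def test_lwr_identical_to_gap_keeping_oracle(self, tiny_fixture):
        """Dropping gap columns changes every edge's logL by the same
        constant, so LWRs match an evaluation that keeps gap columns."""
        tree, aln, model, placer = (tiny_fixture[k] for k in
                                    ("tree", "aln", "model", "placer"))
        read = make_fragment_read(placer, aln, tree.leaf_names[1], 20, 60)
        cands = placer.exhaustive_search(read)
        ours = likelihood_weight_ratios({c.edge: c.log_like for c in cands})
        # oracle: full-likelihood evaluation including gap columns as
        # missing-data tips, at the same optimized (a, b)
        full = {}
        for c in cands:
            read_full = mask_query(read.name, read.aligned, aln.alphabet,
                                   aln.n_columns)
            read_full.mask = np.arange(aln.n_columns)
            read_full.indicator = np.ones((aln.n_columns, 4))
            for i, col in enumerate(read.mask):
                read_full.indicator[col] = read.indicator[i]
            full[c.edge] = float(attachment_loglike_grid(
                placer.cache, c.edge, read_full.indicator, read_full.mask,
                [c.attach_a], [c.pendant_b])[0, 0])
        oracle = likelihood_weight_ratios(full)
        for e in ours:
            assert ours[e] == pytest.approx(oracle[e], abs=1e-9)

    def test_gap_columns_do_not_shift_scores(self, tiny_fixture):
        tree, aln, model, placer = (tiny_fixture[k] for k in
                                    ("tree", "aln", "model", "placer"))
        read = make_fragment_read(placer, aln, tree.leaf_names[0], 10, 50)
        base = [placer.quick_eval(read, e) for e in range(tree.n_edges)]
        padded_rows = {k: v + "----" for k, v in aln.rows.items()}
        aln2 = ReferenceAlignment(padded_rows, aln.alphabet)
        placer2 = Placer(tree, aln2, model)
        read2 = placer2.make_read(read.name, read.aligned + "----")
        padded = [placer2.quick_eval(read2, e) for e in range(tree.n_edges)]
        assert np.allclose(base, padded, atol=1e-9)


class TestQuickEval:
    def test_deterministic(self, small_fixture):
        placer, aln, tree = (small_fixture[k] for k in ("placer", "aln", "tree"))
        read = make_fragment_read(placer, aln, tree.leaf_names[3], 50, 100)
        assert placer.quick_eval(read, 2) == placer.quick_eval(read, 2)
        assert placer.quick_eval_all(read)[2] == placer.quick_eval(read, 2)

    def test_is_a_true_likelihood_at_the_midpoint(self, tiny_fixture):
        """quick_eval equals the naive three-part likelihood at a=A/2, b=b0."""
        tree, aln, model, placer = (tiny_fixture[k] for k in
                                    ("tree", "aln", "model", "placer"))
        read = make_fragment_read(placer, aln, tree.leaf_names[2], 30, 60)
        for e in range(0, tree.n_edges, 2):
            oracle = placement_loglike(tree, aln, model, read, e,
                                       tree.lengths[e] / 2, placer.b0)
            assert placer.quick_eval(read, e) == pytest.approx(oracle, abs=1e-9)

    def test_leaf_sequence_ranks_its_pendant_edge_highly(self):
        """A query equal to a full leaf sequence bats its own edge top-3."""
        hits = 0
        for seed in range(20):
            tree, aln, model, _ = simeval.make_fixture(8, 200, seed=300 + seed)
            placer = Placer(tree, aln, model)
            name = tree.leaf_names[seed % 8]
            read = placer.make_read("q", aln.rows[name])
            node = next(v for v, n in tree.leaf_name.items() if n == name)
            order = placer.batting_order(read)
            if order.index(node - 1) < 3:
                hits += 1
        assert hits == 20


class TestFullEval:
    def test_zero_length_edge_forces_attachment_at_origin(self, tiny_fixture):
        tree, aln, model = (tiny_fixture[k] for k in ("tree", "aln", "model"))
        squashed = tree.with_branch_lengths(tree.lengths.copy())
        squashed.lengths[2] = 0.0
        placer = Placer(squashed, aln, model)
        read = make_fragment_read(placer, aln, tree.leaf_names[1], 10, 60)
        cand = placer.full_eval(read, 2)
        assert cand.attach_a == 0.0

    def test_optimum_dominates_quick_eval(self, small_fixture):
        placer, aln, tree = (small_fixture[k] for k in ("placer", "aln", "tree"))
        read = make_fragment_read(placer, aln, tree.leaf_names[5], 80, 120)
        for e in range(0, tree.n_edges, 3):
            assert placer.full_eval(read, e).log_like \
                >= placer.quick_eval(read, e) - 1e-9

    def test_matches_dense_grid_search(self):
        """Optimized logL within grid resolution of a 200x200 search."""
        for seed in range(10):
            tree, aln, model, _ = simeval.make_fixture(6, 150, seed=400 + seed)
            placer = Placer(tree, aln, model)
            rng = np.random.default_rng(seed)
            taxon = tree.leaf_names[rng.integers(6)]
            read = make_fragment_read(placer, aln, taxon,
                                      int(rng.integers(0, 80)), 60)
            edge = int(rng.integers(tree.n_edges))
            cand = placer.full_eval(read, edge)
            a_grid = np.linspace(0, tree.lengths[edge], 200)
            b_grid = np.linspace(0, placer.b_max, 200)
            grid = attachment_loglike_grid(placer.cache, edge, read.indicator,
                                           read.mask, a_grid, b_grid)
            # grid points are feasible, so the optimizer may exceed the grid
            # max slightly; it must never fall below it by more than the
            # grid's own resolution
            assert cand.log_like >= grid.max() - 0.01


class TestBaseball:
    def _scripted_placer(self, small_fixture, logls):
        """A placer whose batting order and optimized scores are forced."""
        placer = Placer(small_fixture["tree"], small_fixture["aln"],
                        small_fixture["model"], cache=small_fixture["placer"].cache)
        placer.batting_order = lambda read: list(range(len(logls)))
        placer.full_eval = lambda read, e, warm_start=None: PlacementCandidate(
            e, 0.0, 0.1, logls[e])
        return placer

    def test_strike_rule_worked_example(self, small_fixture):
        """Scores (-10,-11,-20,-12,...), D=5, one strike: stop at the third."""
        placer = self._scripted_placer(small_fixture, [-10, -11, -20, -12, -13])
        cands = placer.baseball_search(
            None, BaseballParams(strike_box=5, max_strikes=1, max_pitches=100))
        assert [c.edge for c in cands] == [0, 1, 2]

    def test_infinite_strike_box_is_exhaustive(self, small_fixture):
        placer, aln, tree = (small_fixture[k] for k in ("placer", "aln", "tree"))
        read = make_fragment_read(placer, aln, tree.leaf_names[2], 100, 120)
        relaxed = BaseballParams(strike_box=np.inf, max_strikes=1,
                                 max_pitches=tree.n_edges)
        cands = placer.baseball_search(read, relaxed)
        exhaustive = placer.exhaustive_search(read)
        assert {c.edge for c in cands} == {c.edge for c in exhaustive}
        by_edge = {c.edge: c for c in exhaustive}
        for c in cands:
            assert c.log_like == pytest.approx(by_edge[c.edge].log_like, abs=1e-9)

    def test_single_pitch_returns_top_of_batting_order(self, small_fixture):
        placer, aln, tree = (small_fixture[k] for k in ("placer", "aln", "tree"))
        read = make_fragment_read(placer, aln, tree.leaf_names[4], 60, 150)
        cands = placer.baseball_search(
            read, BaseballParams(strike_box=5, max_strikes=3, max_pitches=1))
        assert len(cands) == 1
        assert cands[0].edge == placer.batting_order(read)[0]

    def test_work_bound(self, small_fixture):
        placer = Placer(small_fixture["tree"], small_fixture["aln"],
                        small_fixture["model"],
                        cache=small_fixture["placer"].cache)
        read = make_fragment_read(placer, small_fixture["aln"],
                                  small_fixture["tree"].leaf_names[1], 30, 100)
        params = BaseballParams(strike_box=3, max_strikes=2, max_pitches=5)
        cands = placer.baseball_search(read, params)
        assert len(cands) <= min(params.max_pitches,
                                 small_fixture["tree"].n_edges)

    def test_heuristic_finds_exhaustive_top_edge(self):
        """Baseball (D=10, 3 strikes) agrees with exhaustive search on the
        top edge for nearly all random reads."""
        agree = total = 0
        for seed in range(6):
            tree, aln, model, _ = simeval.make_fixture(10, 250, seed=500 + seed)
            placer = Placer(tree, aln, model)
            rng = np.random.default_rng(seed)
            for _ in range(5):
                taxon = tree.leaf_names[rng.integers(10)]
                read = make_fragment_read(placer, aln, taxon,
                                          int(rng.integers(0, 130)), 100)
                heur = placer.baseball_search(
                    read, BaseballParams(strike_box=10, max_strikes=3,
                                         max_pitches=tree.n_edges))
                exh = placer.exhaustive_search(read)
                total += 1
                best_h = max(heur, key=lambda c: c.log_like).edge
                best_e = max(exh, key=lambda c: c.log_like).edge
                agree += best_h == best_e
        assert agree / total >= 0.95


class TestFriends:
    def test_identical_reads_copy_placements(self, small_fixture):
        placer, aln, tree = (small_fixture[k] for k in ("placer", "aln", "tree"))
        r1 = make_fragment_read(placer, aln, tree.leaf_names[2], 50, 120, "a")
        r2 = make_fragment_read(placer, aln, tree.leaf_names[2], 50, 120, "b")
        links = find_friends([r1, r2])
        assert links["b"].friend == "a" and links["b"].identical
        out = placer.place_all([r1, r2])
        c1, c2 = out[0].candidates, out[1].candidates
        assert [(c.edge, c.log_like, c.attach_a, c.pendant_b) for c in c1] \
            == [(c.edge, c.log_like, c.attach_a, c.pendant_b) for c in c2]

    def test_dissimilar_reads_have_no_friends(self, small_fixture):
        placer, aln, tree = (small_fixture[k] for k in ("placer", "aln", "tree"))
        r1 = make_fragment_read(placer, aln, tree.leaf_names[0], 0, 100, "a")
        r2 = make_fragment_read(placer, aln, tree.leaf_names[7], 150, 100, "b")
        assert find_friends([r1, r2], threshold=0.99) == {}

    def test_friend_acceleration_is_exact(self, small_fixture):
        """Warm starts change optimizer paths, not results."""
        placer, aln, tree = (small_fixture[k] for k in ("placer", "aln", "tree"))
        rng = np.random.default_rng(8)
        reads = []
        for i in range(12):
            taxon = tree.leaf_names[rng.integers(8)]
            start = int(rng.integers(0, 150))
            reads.append(make_fragment_read(placer, aln, taxon, start, 120,
                                            f"q{i}"))
        with_f = placer.place_all(reads, friends=True)
        without = placer.place_all(reads, friends=False)
        for a, b in zip(with_f, without):
            assert a.best.edge == b.best.edge
            assert a.best.log_like == pytest.approx(b.best.log_like, abs=1e-6)


class TestPlaceAll:
    def test_empty_read_list(self, small_fixture):
        assert small_fixture["placer"].place_all([]) == []

    def test_exhaustive_eval_count_is_edge_count(self, small_fixture):
        tree, aln, model = (small_fixture[k] for k in ("tree", "aln", "model"))
        placer = Placer(tree, aln, model, cache=small_fixture["placer"].cache)
        reads = [make_fragment_read(placer, aln, tree.leaf_names[i], 40, 120,
                                    f"q{i}") for i in range(3)]
        placer.place_all(reads, params=BaseballParams(enabled=False),
                         friends=False)
        assert placer.n_full_evals == 3 * (2 * tree.n_leaves - 3)

    def test_deterministic_placement_file(self, small_fixture):
        placer, aln, tree = (small_fixture[k] for k in ("placer", "aln", "tree"))
        reads = [make_fragment_read(placer, aln, tree.leaf_names[i], 30, 140,
                                    f"q{i}") for i in range(3)]
        texts = []
        for _ in range(2):
            ps = placer.place_all(reads, posterior=True)
            run = PlacementRun(tree.newick(edge_numbers=True),
                               small_fixture["model_text"], ps)
            texts.append(write_place(run))
        assert texts[0] == texts[1]


@pytest.fixture(scope="module")
def tuning(small_fixture):
    placer, aln, tree = (small_fixture[k] for k in ("placer", "aln", "tree"))
    rng = np.random.default_rng(13)
    reads = [make_fragment_read(placer, aln,
                                tree.leaf_names[rng.integers(8)],
                                int(rng.integers(0, 150)), 110, f"q{i}")
             for i in range(8)]
    grid_D, grid_s = [1.0, 5.0, np.inf], [1, 2, 3]
    return placer, reads, placer.fantasy_baseball(reads, grid_D, grid_s)


class TestFantasyBaseball:
    def test_infinite_strike_box_always_finds_optimum(self, tuning):
        _, _, df = tuning
        cell = df[(df.strike_box == np.inf)]
        assert (cell.optimal_found_frac == 1.0).all()

    def test_eval_counts_monotone_in_parameters(self, tuning):
        _, _, df = tuning
        for s in df.max_strikes.unique():
            sub = df[df.max_strikes == s].sort_values("strike_box")
            assert sub.mean_evals.is_monotonic_increasing
        for D in df.strike_box.unique():
            sub = df[df.strike_box == D].sort_values("max_strikes")
            assert sub.mean_evals.is_monotonic_increasing

    def test_replay_matches_direct_rerun(self, tuning):
        placer, reads, df = tuning
        for _, row in df[df.strike_box < np.inf].iloc[:5].iterrows():
            params = BaseballParams(strike_box=row.strike_box,
                                    max_strikes=int(row.max_strikes),
                                    max_pitches=10 ** 6)
            evals = [len(placer.baseball_search(r, params)) for r in reads]
            assert np.mean(evals) == pytest.approx(row.mean_evals)
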