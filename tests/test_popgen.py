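import itertools

import numpy as np
import pytest

from codonburst import popgen, simulate

from .oracles import oracle_hwe_exact


class TestDiversity:
    def test_identical_haplotypes(self):
        d = popgen.diversity(["ACGT" * 5] * 4)
        assert d.S == 0 and d.pi == 0.0 and d.tajima_D is None

    def test_two_haplotypes_two_differences(self):
        a = "A" * 100
        b = "T" + "A" * 98 + "T"
        d = popgen.diversity([a, b])
        assert d.pi == pytest.approx(0.02)
        assert d.k_hat == pytest.approx(2.0)

    def test_hand_worked_tajima_d_n4(self):
        """n=4, length 10, S=3, pairwise differences {1,2,3,1,2,1}:
        D evaluates to about +0.168 under the 1989 constants."""
        haps = ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAGAT", "AAAAAACGAT"]
        d = popgen.diversity(haps)
        assert d.S == 3
        assert d.k_hat == pytest.approx(5 / 3)
        assert d.tajima_D == pytest.approx(0.168, abs=0.001)

    def test_too_few_haplotypes(self):
        with pytest.raises(ValueError):
            popgen.diversity(["ACGT"])

    def test_gap_columns_removed_before_counting(self):
        d = popgen.diversity(["AC-T", "ACGT", "TCNT"])
        # columns 2 (gap) and 2? -> kept columns are 0,1,3; only col 0 varies
        assert d.counted_length == 3
        assert d.S == 1

    def test_k_hat_matches_sitewise_identity(self, rng):
        """k_hat equals the sum over sites of 2p(1-p)n/(n-1) (unbiased
        heterozygosity identity), on random samples."""
        for _ in range(100):
            n, L = 6, 40
            arr = rng.integers(0, 2, size=(n, L))
            haps = ["".join("AT"[v] for v in row) for row in arr]
            d = popgen.diversity(haps)
            expected = 0.0
            for j in range(L):
                p = arr[:, j].mean()
                expected += 2 * p * (1 - p) * n / (n - 1)
            assert d.k_hat == pytest.approx(expected, abs=1e-9)

    def test_neutral_coalescent_calibration(self):
        """On neutral coalescent replicates (n=20, theta=5), Tajima's D is
        centred near 0 with moderate variance."""
        Ds = []
        for seed in range(200):
            haps = simulate.simulate_neutral_sample(20, 5.0, 2000, seed=seed)
            d = popgen.diversity(haps)
            if d.tajima_D is not None:
                Ds.append(d.tajima_D)
        assert abs(np.mean(Ds)) < 0.15
        assert np.var(Ds) < 1.5


class TestSlidingWindows:
    def test_uniform_alignment_all_zero(self):
        w = popgen.sliding_windows(["A" * 200] * 4, window=100, step=25)
        assert all(x.stats.pi == 0.0 for x in w)

    def test_windows_tile_with_fixed_step(self):
        w = popgen.sliding_windows(["A" * 200, "T" * 200], window=100, step=50)
        assert [x.start for x in w] == [0, 50, 100]
        assert w[0].end - w[0].start == 100
        assert w[-1].end == 200
        # unaligned length: truncated terminal window
        w2 = popgen.sliding_windows(["A" * 130, "T" * 130], window=100, step=50)
        assert (w2[-1].start, w2[-1].end) == (50, 130)

    def test_divergent_block_is_argmax_pi(self):
        sim = simulate.simulate_dimorphic_population(
            simulate.PopulationSimConfig(seed=4)
        )
        haps = sim.sample.haplotypes()
        windows = popgen.sliding_windows(haps, window=100, step=25)
        best = max(windows, key=lambda x: x.stats.pi)
        # divergence is confined to the coding and flank blocks by design;
        # the top window must overlap one of the seeded divergent sites
        div_sites = {s for s, _, _ in sim.diagnostic_sites}
        assert any(best.start <= s < best.end for s in div_sites) or best.start >= 900

    def test_concatenation_partitions_difference_totals(self):
        haps = ["ACGTACGTAC", "ACCTACGAAC", "ACGAACGTTC"]
        full = popgen.diversity(haps)
        parts = popgen.sliding_windows(haps, window=5, step=5)
        assert sum(w.stats.k_hat for w in parts) == pytest.approx(full.k_hat)

    def test_oversized_window_collapses_to_one(self):
        w = popgen.sliding_windows(["ACGT", "ACGA"], window=100, step=1)
        assert len(w) == 1 and w[0].end == 4


class TestLinkageDisequilibrium:
    def test_complete_association(self):
        r = popgen.ld_from_counts(50, 0, 0, 50)
        assert r.D == pytest.approx(0.25)
        assert r.D_prime == pytest.approx(1.0)

    def test_independence(self):
        r = popgen.ld_from_counts(25, 25, 25, 25)
        assert r.D == pytest.approx(0.0)
        assert r.D_prime == pytest.approx(0.0)

    def test_partial_association_worked_example(self):
        r = popgen.ld_from_counts(40, 10, 10, 40)
        assert r.D == pytest.approx(0.15)
        assert r.D_prime == pytest.approx(0.6)
        assert r.p_two_tailed < 0.001

    def test_dprime_bounds_and_one_empty_cell(self, rng):
        for _ in range(50):
            c = rng.integers(0, 30, size=4)
            c[rng.integers(0, 4)] = 0
            rowa, rowb = c[0] + c[1], c[2] + c[3]
            cola, colb = c[0] + c[2], c[1] + c[3]
            if 0 in (rowa + cola, ) or min(rowa + rowb, cola + colb) == 0:
                continue
            try:
                r = popgen.ld_from_counts(*c)
            except ValueError:
                continue  # monomorphic draw
            assert 0.0 <= r.D_prime <= 1.0 + 1e-12
            assert abs(r.D) <= 0.25 + 1e-12
            assert r.D_prime == pytest.approx(1.0)

    def test_region_dimorphism_labels(self):
        labels_a = ["I"] * 30 + ["II"] * 30
        labels_b = ["I"] * 30 + ["II"] * 30
        r = popgen.ld_two_loci(labels_a, labels_b, "coding", "flank3")
        assert r.D_prime == pytest.approx(1.0)
        assert r.locus_a == "coding"

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(ValueError):
            popgen.ld_two_loci(["I"] * 10, ["I"] * 5 + ["II"] * 5)


class TestHardyWeinberg:
    def test_exact_hw_proportions_chi2(self):
        assert popgen.hwe_test(25, 50, 25, method="chi2") == pytest.approx(1.0)

    def test_monomorphic_returns_one(self):
        assert popgen.hwe_test(17, 0, 0) == 1.0

    def test_no_heterozygotes_matches_enumeration(self):
        p = popgen.hwe_test(50, 0, 50)
        assert p == pytest.approx(oracle_hwe_exact(50, 0, 50), rel=1e-9)
        assert p < 1e-6  # extreme heterozygote deficit

    def test_exact_matches_enumeration_all_small_totals(self):
        """Exact conditional p equals full enumeration for every genotype
        configuration with total <= 50 (coarse grid above 25)."""
        totals = list(range(1, 26)) + [30, 40, 50]
        for N in totals:
            for n_AA in range(0, N + 1, max(1, N // 10)):
                for n_Aa in range(0, N - n_AA + 1, max(1, N // 10)):
                    n_aa = N - n_AA - n_Aa
                    p = popgen.hwe_test(n_AA, n_Aa, n_aa)
                    q = oracle_hwe_exact(n_AA, n_Aa, n_aa)
                    assert p == pytest.approx(q, abs=1e-9), (n_AA, n_Aa, n_aa)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            popgen.hwe_test(-1, 2, 3)

    def test_hw_calibration_under_null(self):
        """Genotypes drawn under Hardy-Weinberg proportions rarely reject."""
        rng = np.random.default_rng(99)
        ok = 0
        reps = 100
        for _ in range(reps):
            g = rng.choice(3, size=1000, p=[0.25, 0.5, 0.25])
            counts = [(g == k).sum() for k in range(3)]
            ok += popgen.hwe_test(*counts) > 0.01
        assert ok / reps >= 0.95


class TestCladeAssignment:
    DIAG = [(0, "A", "T"), (5, "C", "G"), (9, "A", "C")]

    def test_pure_haplotypes(self):
        haps = ["ACGTACGTAA", "TCGTAGGTAC"]
        out = popgen.assign_clades(haps, self.DIAG)
        assert out.labels == ["I", "II"]

    def test_mixture_unassigned(self):
        # 2/3 of diagnostic sites clade I, threshold 0.9 -> unassigned
        hap = "ACGTACGTAC"  # sites: I, I, II
        out = popgen.assign_clades([hap], self.DIAG)
        assert out.labels == ["unassigned"]

    def test_empty_diagnostics_rejected(self):
        with pytest.raises(ValueError):
            popgen.assign_clades(["AAAA"], [])

    def test_recovers_simulated_clades(self):
        sim = simulate.simulate_dimorphic_population(
            simulate.PopulationSimConfig(seed=8, within_clade_mutations=0.3)
        )
        haps = sim.sample.haplotypes("coding")
        out = popgen.assign_clades(haps, sim.diagnostic_sites)
        assert out.labels == sim.true_clades


class TestHaplotypeNetwork:
    def test_single_step_path(self):
        net = popgen.build_network({"a": "AAA", "b": "AAT", "c": "ATT"},
                                   connection_limit=5)
        assert sorted(net.edges) == [("a", "b"), ("b", "c")]
        assert not any(v["inferred"] for v in net.nodes.values())

    def test_two_step_pair_gets_one_connector(self):
        net = popgen.build_network({"a": "AAA", "b": "ATT"}, connection_limit=5)
        inferred = [k for k, v in net.nodes.items() if v["inferred"]]
        assert len(inferred) == 1 and len(net.edges) == 2

    def test_star_center_degree(self):
        center = "AAAAAA"
        alleles = {"c": center}
        for i in range(4):
            alleles[f"s{i}"] = center[:i] + "T" + center[i + 1 :]
        net = popgen.build_network(alleles, frequencies={"c": 10}, connection_limit=5)
        assert net.degree("c") == 4

    def test_beyond_limit_stays_disconnected(self):
        net = popgen.build_network({"a": "AAAAAA", "b": "TTTTTT"}, connection_limit=2)
        assert len(net.components()) == 2

    def test_msn_contains_a_minimum_spanning_tree(self, rng):
        """The network always contains a spanning tree over observed
        alleles whose step total equals the exhaustively enumerated
        minimum spanning weight (<= 6 alleles)."""
        checked = 0
        for rep in range(20):
            seqs = {}
            while len(set(seqs.values())) < 5:
                s = "".join("ACGT"[v] for v in rng.integers(0, 2, size=8))
                seqs[f"a{len(seqs)}"] = s
                seqs = {k: v for k, v in seqs.items()}
                if len(set(seqs.values())) < len(seqs):
                    seqs.popitem()
            ids = list(seqs)
            n = len(ids)

            def hamming(u, v):
                return sum(x != y for x, y in zip(seqs[u], seqs[v]))

            # exhaustive minimum spanning weight over observed alleles
            best = min(
                (
                    sum(hamming(u, v) for u, v in tree_edges)
                    for tree_edges in itertools.combinations(
                        itertools.combinations(ids, 2), n - 1
                    )
                    if self._is_spanning(tree_edges, ids)
                ),
            )
            net = popgen.build_network(seqs, connection_limit=100)
            assert len(net.components()) == 1
            # contract inferred chains into weighted observed-observed edges
            contracted = self._contract(net)
            mst = self._kruskal_weight(contracted, ids)
            assert mst == best
            checked += 1
        assert checked >= 10

    @staticmethod
    def _is_spanning(tree_edges, ids):
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for u, v in tree_edges:
            ru, rv = find(u), find(v)
            if ru == rv:
                return False
            parent[ru] = rv
        return True

    @staticmethod
    def _contract(net):
        """Walk inferred chains to recover observed-to-observed step weights."""
        adj = {}
        for u, v in net.edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        observed = [k for k, a in net.nodes.items() if not a["inferred"]]
        out = []
        seen_chains = set()
        for start in observed:
            for nb in adj.get(start, []):
                steps = 1
                prev, cur = start, nb
                while net.nodes[cur]["inferred"]:
                    nxt = [x for x in adj[cur] if x != prev][0]
                    prev, cur = cur, nxt
                    steps += 1
                key = (min(start, cur), max(start, cur), steps)
                if key not in seen_chains:
                    seen_chains.add(key)
                    out.append((start, cur, steps))
        return out

    @staticmethod
    def _kruskal_weight(edges, ids):
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        total = 0
        for u, v, w in sorted(edges, key=lambda e: e[2]):
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
                total += w
        return total

    def test_parsimony95_limit_grows_with_length(self):
        assert popgen.parsimony95_limit(100) < popgen.parsimony95_limit(1000)
        assert popgen.parsimony95_limit(600) >= 5

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            popgen.build_network({"a": "AA"}, connection_limit=3)
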