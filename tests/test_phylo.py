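import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from madcpop import phylo, popgen
from madcpop.snps import VariantRecord


# ---------------------------------------------------------------------------
# independent TN93 oracle: scalar loops and the printed closed form, coded
# separately from the implementation


def tn93_oracle(sa, sb):
    pairs = [(x, y) for x, y in zip(sa, sb) if x != "N" and y != "N"]
    n = len(pairs)
    freq = {b: 0 for b in "ACGT"}
    for x, y in pairs:
        freq[x] += 1
        freq[y] += 1
    gA, gC, gG, gT = (freq[b] / (2 * n) for b in "ACGT")
    gR, gY = gA + gG, gC + gT
    p1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / n
    p2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / n
    q = sum(1 for x, y in pairs if x != y and ((x in "AG") != (y in "AG"))) / n
    t1 = -(2 * gA * gG / gR) * math.log(1 - gR * p1 / (2 * gA * gG) - q / (2 * gR))
    t2 = -(2 * gC * gT / gY) * math.log(1 - gY * p2 / (2 * gC * gT) - q / (2 * gY))
    t3 = -2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY) * math.log(1 - q / (2 * gR * gY))
    return t1 + t2 + t3


def _random_seq_pair(rng, n=1000, sub_rate=0.1):
    a = rng.choice(list("ACGT"), n)
    b = a.copy()
    muts = rng.random(n) < sub_rate
    for i in np.flatnonzero(muts):
        b[i] = rng.choice([x for x in "ACGT" if x != a[i]])
    return "".join(a), "".join(b)


class TestTamuraNei:
    def test_identical_sequences_zero(self):
        assert phylo.tamura_nei_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_matches_independent_formula_evaluation(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            a, b = _random_seq_pair(rng)
            assert phylo.tamura_nei_distance(a, b) == pytest.approx(tn93_oracle(a, b), abs=1e-10)

    def test_pairwise_deletion_of_n_sites(self):
        a = "ACGTNCGT"
        b = "ACGTAAGT"  # offset 4 masked by N in a; real difference at offset 5
        c = tn93_oracle(a, b)
        assert phylo.tamura_nei_distance(a, b) == pytest.approx(c, abs=1e-12)

    def test_reduces_to_jukes_cantor_under_equal_rates(self):
        # equal base freqs, P1 = P2 = p/6, Q = 2p/3 -> d = -3/4 ln(1 - 4p/3);
        # substitutions are balanced (x->y matched by y->x) so the averaged
        # composition stays uniform
        block = "ACGT" * 300
        b = list(block)
        a_sites = [4 * k for k in range(300)]
        c_sites = [4 * k + 1 for k in range(300)]
        g_sites = [4 * k + 2 for k in range(300)]
        t_sites = [4 * k + 3 for k in range(300)]
        for i in a_sites[:15]:
            b[i] = "G"
        for i in g_sites[:15]:
            b[i] = "A"
        for i in c_sites[:15]:
            b[i] = "T"
        for i in t_sites[:15]:
            b[i] = "C"
        for i in a_sites[15:45]:
            b[i] = "C"
        for i in c_sites[15:45]:
            b[i] = "A"
        for i in g_sites[15:45]:
            b[i] = "T"
        for i in t_sites[15:45]:
            b[i] = "G"
        sa, sb = block, "".join(b)
        p = 180 / 1200
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert phylo.tamura_nei_distance(sa, sb) == pytest.approx(jc, abs=1e-8)

    def test_saturation_raises(self):
        with pytest.raises(phylo.SaturationError):
            phylo.tamura_nei_distance("A" * 100, "C" * 100)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            phylo.tamura_nei_distance("NNN", "ACG")


# ---------------------------------------------------------------------------
# NJ


def _patristic(newick, taxa):
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    pdm = tree.phylogenetic_distance_matrix()
    out = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            d = pdm.patristic_distance(tns.get_taxon(a), tns.get_taxon(b))
            out.loc[a, b] = out.loc[b, a] = d
    return out


def _random_additive_matrix(rng, n_taxa):
    """Random binary tree with random branch lengths; returns leaf distances."""
    nodes = [{i} for i in range(n_taxa)]
    dist = np.zeros((n_taxa, n_taxa))
    pend = rng.uniform(0.1, 2.0, n_taxa)
    for i in range(n_taxa):
        for j in range(n_taxa):
            if i != j:
                dist[i, j] += pend[i] + pend[j]
    active = list(range(n_taxa))
    members = {i: {i} for i in range(n_taxa)}
    while len(active) > 2:
        i, j = sorted(rng.choice(active, 2, replace=False))
        extra = rng.uniform(0.1, 1.5)
        merged = members[i] | members[j]
        for a in merged:
            for b in range(n_taxa):
                if b not in merged:
                    dist[a, b] += extra
                    dist[b, a] += extra
        active.remove(j)
        members[i] = merged
    labels = [f"t{i}" for i in range(n_taxa)]
    return pd.DataFrame(dist, index=labels, columns=labels)


class TestNeighborJoining:
    def test_four_taxon_additive_recovered_exactly(self):
        # tree ((A:1,B:2):1,C:3,D:4) with internal edge 1
        labels = list("ABCD")
        d = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], index=labels, columns=labels, dtype=float
        )
        tree = phylo.nj_tree(d)
        back = _patristic(tree.newick, labels)
        assert np.allclose(back.to_numpy(), d.to_numpy(), atol=1e-9)
        t = tree.as_dendropy()
        t.encode_bipartitions()
        splits = {frozenset(lf.taxon.label for lf in e.head_node.leaf_iter()) for e in t.preorder_edge_iter() if e.head_node is not t.seed_node}
        assert frozenset("AB") in splits or frozenset("CD") in splits

    def test_three_taxa_closed_form(self):
        labels = list("XYZ")
        d = pd.DataFrame([[0, 4, 6], [4, 0, 8], [6, 8, 0]], index=labels, columns=labels, dtype=float)
        tree = phylo.nj_tree(d)
        back = _patristic(tree.newick, labels)
        # lX=(4+6-8)/2=1, lY=(4+8-6)/2=3, lZ=(6+8-4)/2=5
        assert np.allclose(back.to_numpy(), d.to_numpy(), atol=1e-12)

    def test_random_additive_trees_reconstructed(self):
        rng = np.random.default_rng(33)
        for n_taxa in (4, 5, 6, 7, 8):
            d = _random_additive_matrix(rng, n_taxa)
            tree = phylo.nj_tree(d)
            back = _patristic(tree.newick, list(d.index))
            assert np.abs(back.to_numpy() - d.to_numpy()).max() < 1e-9

    def test_non_symmetric_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            phylo.nj_tree(d)

    def test_missing_entries_rejected(self):
        d = pd.DataFrame([[0, np.nan, 2], [np.nan, 0, 1], [2, 1, 0]], dtype=float, index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="missing"):
            phylo.nj_tree(d)


# ---------------------------------------------------------------------------
# sequences, bootstrap, species tree, outliers


def _variants_and_dm(dosages, seed=0):
    rng = np.random.default_rng(seed)
    n, m = dosages.shape
    variants = []
    cols = {}
    bases = list("ACGT")
    for j in range(m):
        ref = bases[int(rng.integers(4))]
        alt = rng.choice([b for b in bases if b != ref])
        ad = np.zeros((n, 2), dtype=np.int64)
        for i in range(n):
            d = dosages[i, j]
            if np.isnan(d):
                continue
            depth = 30
            a = int(round(depth * d / 2))
            ad[i] = (depth - a, a)
        v = VariantRecord("chr1.1", 10 * (j + 1), f"L{j}", 0, ref, [str(alt)], True, ad)
        variants.append(v)
        cols[v.vcf_id] = dosages[:, j]
    values = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    return variants, popgen.DosageMatrix(values, 10, 0.01)


class TestSampleSequences:
    def test_dosage_to_base_mapping(self):
        dosages = np.array([[0.0, 2.0, np.nan]])
        variants, dm = _variants_and_dm(dosages)
        seqs = phylo.sample_sequences(dm, variants)
        expected = variants[0].ref_base + variants[1].alt_bases[0] + "N"
        assert seqs["s0"] == expected

    def test_het_resolved_by_read_majority(self):
        def one_het(ad):
            v = VariantRecord("chr1.1", 10, "L0", 0, "A", ["G"], True, np.array(ad))
            dm = popgen.DosageMatrix(pd.DataFrame({"L0:0": [1.0]}, index=["s0"]), 10, 0.01)
            return phylo.sample_sequences(dm, [v])["s0"]

        assert one_het([[2, 9]]) == "G"
        assert one_het([[9, 2]]) == "A"
        assert one_het([[5, 5]]) == "A"  # tie -> reference


def _two_species_dosage(theta, n_per, m, seed):
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.95, m)
    scale = (1 - theta) / theta
    out = []
    for _ in range(2):
        p = rng.beta(p0 * scale, (1 - p0) * scale)
        out.append((rng.binomial(1, p, (n_per, m)) + rng.binomial(1, p, (n_per, m))).astype(float))
    return np.vstack(out)


class TestBootstrap:
    def test_same_seed_identical_supports(self):
        variants, dm = _variants_and_dm(_two_species_dosage(0.4, 5, 80, 3))
        t1 = phylo.bootstrap_support(dm, variants, n_reps=20, seed=5)
        t2 = phylo.bootstrap_support(dm, variants, n_reps=20, seed=5)
        assert t1.newick == t2.newick and t1.support == t2.support

    def test_no_replicates_no_support(self):
        variants, dm = _variants_and_dm(_two_species_dosage(0.4, 4, 60, 4))
        tree = phylo.bootstrap_support(dm, variants, n_reps=0, seed=0)
        assert tree.support == {}

    def test_clear_species_split_high_support(self):
        variants, dm = _variants_and_dm(_two_species_dosage(0.48, 6, 300, 6))
        tree = phylo.bootstrap_support(dm, variants, n_reps=50, seed=1)
        t = tree.as_dendropy()
        # find the bipartition separating s0-s5 from s6-s11 and check its label
        want = {f"s{i}" for i in range(6)}
        found = None
        for node in t.preorder_node_iter():
            leaves = {lf.taxon.label for lf in node.leaf_iter() if lf.taxon}
            if leaves == want or leaves == {f"s{i}" for i in range(6, 12)}:
                found = node.label
        assert found is not None and float(found) >= 95

    def test_stronger_divergence_stronger_support(self):
        variants_lo, dm_lo = _variants_and_dm(_two_species_dosage(0.10, 5, 120, 8))
        variants_hi, dm_hi = _variants_and_dm(_two_species_dosage(0.48, 5, 120, 8))

        def split_support(dm, variants):
            tree = phylo.bootstrap_support(dm, variants, n_reps=40, seed=2, support_threshold=0.0)
            t = tree.as_dendropy()
            want = {f"s{i}" for i in range(5)}
            best = 0.0
            for node in t.preorder_node_iter():
                leaves = {lf.taxon.label for lf in node.leaf_iter() if lf.taxon}
                if (leaves == want or leaves == {f"s{i}" for i in range(5, 10)}) and node.label:
                    best = float(node.label)
            return best

        assert split_support(dm_hi, variants_hi) >= split_support(dm_lo, variants_lo)


class TestFstSpeciesTree:
    def test_sister_pair_resolved_and_rooted(self):
        labels = ["A", "B", "C"]
        fst = pd.DataFrame(
            [[0, 0.1, 0.4], [0.1, 0, 0.4], [0.4, 0.4, 0]], index=labels, columns=labels, dtype=float
        )
        tree = phylo.fst_species_tree(fst, root_species="C")
        t = tree.as_dendropy()
        root_children = t.seed_node.child_nodes()
        leaf_children = [c for c in root_children if c.is_leaf()]
        assert any(c.taxon.label == "C" for c in leaf_children)
        ab = [c for c in root_children if not c.is_leaf()]
        assert ab and {lf.taxon.label for lf in ab[0].leaf_iter()} == {"A", "B"}

    def test_missing_entries_listed(self):
        fst = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError, match="missing"):
            phylo.fst_species_tree(fst, "A")


class TestFlagOutliers:
    def _meta(self, species):
        rows = []
        for i, sp in enumerate(species):
            rows.append([f"s{i}", f"acc{i}", sp, "Collection", "single", 1])
        return pd.DataFrame(rows, columns=["sample_id", "accession_id", "species", "source", "role", "plant_count"])

    def _block_dist(self, n_a, n_b, within=0.01, between=1.0):
        n = n_a + n_b
        d = np.full((n, n), between)
        d[:n_a, :n_a] = within
        d[n_a:, n_a:] = within
        np.fill_diagonal(d, 0)
        labels = [f"s{i}" for i in range(n)]
        return pd.DataFrame(d, index=labels, columns=labels)

    def test_no_swaps_no_flags(self):
        dist = self._block_dist(6, 6)
        meta = self._meta(["X"] * 6 + ["Y"] * 6)
        assert len(phylo.flag_outliers(dist, meta, k=5)) == 0

    def test_injected_swap_flagged_with_true_species(self):
        dist = self._block_dist(6, 6)
        species = ["X"] * 6 + ["Y"] * 6
        species[0] = "Y"  # s0 genetically X but labeled Y
        meta = self._meta(species)
        flags = phylo.flag_outliers(dist, meta, k=5)
        assert len(flags) == 1
        assert flags.iloc[0].tolist() == ["acc0", "Y", "X"]

    def test_ambiguous_sister_species_suppressed(self):
        # between-species distance indistinguishable from within: neighbours mix
        dist = self._block_dist(6, 6, within=0.5, between=0.5)
        species = ["X"] * 6 + ["Y"] * 6
        species[0] = "Y"
        meta = self._meta(species)
        flags = phylo.flag_outliers(dist, meta, k=5, majority=0.8)
        assert len(flags) == 0

    def test_rare_species_cannot_be_assignment_target(self):
        dist = self._block_dist(1, 6)
        meta = self._meta(["X"] + ["Y"] * 6)  # X has a single accession
        flags = phylo.flag_outliers(dist, meta, k=3)
        assert "X" not in set(flags.get("assigned_species", []))
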