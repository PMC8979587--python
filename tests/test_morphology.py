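"""Tree model, SWC round-trips, on-path metrics and branch complexity."""

import numpy as np
import pytest
from scipy.integrate import quad

from branchfield import morphology as M
from conftest import random_tree, straight_cable


def tree_site(morph, edge, offset=0.5, **kw):
    return M.Site(morph, edge, offset, **kw)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

class TestSwcIO:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("# comment\n1 1 0 0 0 6 -1\n2 3 0 10 0 0.5 1\n3 3 0 20 0 0.5 2\n")
        m = M.read_swc(p)
        assert m.n_nodes() == 3
        assert m.nodes[m.root_id].region == "soma"
        assert len(m.children(1)) == 1 and len(m.children(2)) == 1

    def test_write_read_write_is_byte_stable(self, tmp_path):
        m = random_tree(3)
        p1, p2 = tmp_path / "a.swc", tmp_path / "b.swc"
        M.write_swc(m, p1)
        M.write_swc(M.read_swc(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_roundtrip_preserves_path_distances(self, tmp_path):
        m = random_tree(7, n_nodes=50)
        p = tmp_path / "t.swc"
        M.write_swc(m, p)
        m2 = M.read_swc(p)
        # compare distance-to-root for every node, in original traversal order
        def dists(mm):
            return sorted(
                round(sum(mm.edge_length(e) for e in mm.path_to_root(n)), 6)
                for n in mm.nodes
            )
        assert dists(m) == pytest.approx(dists(m2), abs=1e-4)

    @pytest.mark.parametrize("content,msg", [
        ("1 1 0 0 0 6\n", "7 columns"),
        ("1 9 0 0 0 6 -1\n", "type code"),
        ("1 1 0 0 0 6 -1\n2 1 0 1 0 6 -1\n", "one root"),
        ("1 1 0 0 0 0 -1\n", "radius"),
    ])
    def test_malformed_rejected(self, tmp_path, content, msg):
        p = tmp_path / "bad.swc"
        p.write_text(content)
        with pytest.raises(M.SWCError, match=msg):
            M.read_swc(p)


# ---------------------------------------------------------------------------
# Site metrics
# ---------------------------------------------------------------------------

class TestSiteMetrics:
    def test_tip_of_unbranched_dendrite(self):
        m = straight_cable(12, step=10.0)  # 120 um
        d, order = M.site_metrics(tree_site(m, 13, 1.0))
        assert d == pytest.approx(120.0)
        assert order == 0

    def test_order_counts_on_path_bifurcations(self):
        # root -> a -> b(branch) -> c(branch) -> d ; side children at b and c
        nodes = [M.Node(1, None, (0, 0, 0), 0.5, "dendrite"),
                 M.Node(2, 1, (0, 10, 0), 0.5, "dendrite"),
                 M.Node(3, 2, (0, 20, 0), 0.5, "dendrite"),
                 M.Node(4, 3, (0, 30, 0), 0.5, "dendrite"),
                 M.Node(5, 4, (0, 40, 0), 0.5, "dendrite"),
                 M.Node(6, 3, (10, 20, 0), 0.5, "dendrite"),
                 M.Node(7, 4, (10, 30, 0), 0.5, "dendrite")]
        m = M.Morphology(nodes)
        assert M.site_metrics(tree_site(m, 5, 0.5))[1] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_distance_matches_networkx_shortest_path(self, seed):
        nx = pytest.importorskip("networkx")
        m = random_tree(seed, n_nodes=40)
        g = nx.Graph()
        for e in m.edge_ids():
            g.add_edge(m.nodes[e].parent_id, e, weight=m.edge_length(e))
        rng = np.random.default_rng(seed)
        edges = rng.choice(m.edge_ids(), size=8)
        for e in edges:
            d, _ = M.site_metrics(tree_site(m, int(e), 1.0))
            ref = nx.shortest_path_length(g, m.root_id, int(e), weight="weight")
            assert d == pytest.approx(ref, rel=1e-12)

    def test_planar_mode_underestimates(self):
        m = random_tree(11)
        for e in list(m.edge_ids())[5:10]:
            s = tree_site(m, e, 0.7)
            assert M.site_metrics(s, planar=True)[0] <= M.site_metrics(s)[0] + 1e-12


# ---------------------------------------------------------------------------
# Branch profile beta(x)
# ---------------------------------------------------------------------------

def beta_oracle(site, probes):
    """Independent branch count: insert the site as a graph node, take
    single-source shortest-path node distances, and count the edges whose
    distance span covers each probe."""
    nx = pytest.importorskip("networkx")
    m = site.morphology
    g = nx.Graph()
    spans = []
    c = site.edge_id
    p = m.nodes[c].parent_id
    L = m.edge_length(c)
    for e in m.edge_ids():
        if e == c:
            continue
        g.add_edge(m.nodes[e].parent_id, e, weight=m.edge_length(e))
    g.add_edge("S", p, weight=site.offset * L)
    g.add_edge("S", c, weight=(1 - site.offset) * L)
    dist = nx.single_source_dijkstra_path_length(g, "S", weight="weight")
    for u, v, w in g.edges(data="weight"):
        if w > 0:
            spans.append((min(dist[u], dist[v]), min(dist[u], dist[v]) + w))
    counts = np.zeros(len(probes), dtype=int)
    for a, b in spans:
        counts += (probes >= a) & (probes < b)
    return counts


class TestBranchProfile:
    def test_midpoint_of_cable(self):
        m = straight_cable(10, step=10.0)  # 100 um
        prof = M.branch_profile(tree_site(m, 6, 1.0))  # 50 um from either end
        assert prof.beta(10.0) == 2
        assert prof.beta(49.0) == 2
        assert prof.beta(51.0) == 0
        assert prof.beta(200.0) == 0

    def test_beta_starts_at_two_and_steps_up_past_bifurcation(self):
        # site 20 um proximal to a symmetric bifurcation, long proximal side
        nodes = [M.Node(1, None, (0, 0, 0), 0.5, "dendrite"),
                 M.Node(2, 1, (0, 100, 0), 0.5, "dendrite"),
                 M.Node(3, 2, (0, 120, 0), 0.5, "dendrite"),
                 M.Node(4, 3, (30, 160, 0), 0.5, "dendrite"),
                 M.Node(5, 3, (-30, 160, 0), 0.5, "dendrite")]
        m = M.Morphology(nodes)
        prof = M.branch_profile(tree_site(m, 3, 0.0))  # at node 2, 20 um to branch
        assert prof.beta(5.0) == 2
        assert prof.beta(19.9) == 2
        assert prof.beta(20.1) == 3

    @pytest.mark.parametrize("seed", range(4))
    def test_profile_matches_dense_sampling(self, seed):
        m = random_tree(seed, n_nodes=45)
        rng = np.random.default_rng(seed + 100)
        for e in rng.choice(m.edge_ids(), size=4):
            site = tree_site(m, int(e), float(rng.uniform(0.2, 0.8)))
            prof = M.branch_profile(site)
            probes = np.linspace(0.05, prof.breakpoints[-1] * 1.1, 200)
            # avoid probing exactly on a breakpoint
            probes = probes[np.min(np.abs(probes[:, None] - prof.breakpoints), axis=1) > 1e-6]
            assert np.array_equal(prof.beta(probes), beta_oracle(site, probes))


# ---------------------------------------------------------------------------
# Branch complexity Omega
# ---------------------------------------------------------------------------

def subdivide(morph, pieces=2):
    """Split every edge into `pieces` collinear edges (same geometry)."""
    nodes = [morph.nodes[morph.root_id]]
    next_id = max(morph.nodes) + 1
    id_map = {morph.root_id: morph.root_id}
    for e in morph.topological_order():
        if e == morph.root_id:
            continue
        n = morph.nodes[e]
        p = morph.nodes[n.parent_id]
        prev = id_map[n.parent_id]
        for k in range(1, pieces):
            pos = p.position + (n.position - p.position) * k / pieces
            nodes.append(M.Node(next_id, prev, pos, n.radius, n.region))
            prev = next_id
            next_id += 1
        nodes.append(M.Node(e, prev, n.position, n.radius, n.region))
        id_map[e] = e
    return M.Morphology(nodes)


class TestBranchComplexity:
    def test_centered_cable_closed_form(self):
        m = straight_cable(20, step=10.0)  # 200 um, site at center
        lam = 145.0
        om = M.branch_complexity(tree_site(m, 11, 1.0), lam)
        assert om == pytest.approx(2 * lam * (1 - np.exp(-100 / lam)), rel=1e-12)

    def test_short_tree_limit(self):
        m = straight_cable(2, step=0.01)
        om = M.branch_complexity(tree_site(m, 2, 0.5), 145.0)
        assert 0 < om < 0.1

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_matches_adaptive_quadrature(self, seed):
        m = random_tree(seed, n_nodes=40)
        rng = np.random.default_rng(seed)
        e = int(rng.choice(m.edge_ids()))
        site = tree_site(m, e, 0.5)
        prof = M.branch_profile(site)
        for lam in (5.0, 145.0, 400.0):
            om = M.branch_complexity(site, lam)
            ref = sum(
                quad(lambda x: prof.beta(x) * np.exp(-x / lam), a, b, limit=200)[0]
                for a, b in zip(prof.breakpoints[:-1], prof.breakpoints[1:])
            )
            assert om == pytest.approx(ref, rel=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_invariant_under_edge_subdivision(self, seed):
        m = random_tree(seed, n_nodes=30)
        m2 = subdivide(m, 3)
        # offset 1.0 pins the site to a node position shared by both trees
        e = list(m.edge_ids())[10]
        om1 = M.branch_complexity(tree_site(m, e, 1.0), 145.0)
        om2 = M.branch_complexity(tree_site(m2, e, 1.0), 145.0)
        assert om1 == pytest.approx(om2, rel=1e-9)

    def test_bounds(self):
        for seed in range(4):
            m = random_tree(seed, n_nodes=35)
            total = m.total_length()
            for e in list(m.edge_ids())[::7]:
                om = M.branch_complexity(tree_site(m, e, 0.5), 145.0)
                assert 0 < om <= 2 * 145.0 + total

    def test_lambda_must_be_positive(self):
        m = straight_cable()
        with pytest.raises(ValueError, match="positive"):
            M.branch_complexity(tree_site(m, 5, 0.5), -1.0)

    def test_sweep_returns_per_lambda_table(self):
        m = straight_cable()
        out = M.branch_complexity(tree_site(m, 5, 0.5), [5, 145, 400])
        assert set(out) == {5, 145, 400}
        assert out[5] < out[145] < out[400]


# ---------------------------------------------------------------------------
# Cutting
# ---------------------------------------------------------------------------

class TestCutSubtrees:
    def test_cut_terminal_branch_decreases_omega(self, cell0):
        m = cell0.morphology
        site = cell0.site_high
        term = [e for e in m.edge_ids()
                if not m.children(e) and m.nodes[e].region == "dendrite"
                and e not in m.path_to_root(site.edge_id)]
        m2 = M.cut_subtrees(m, [term[0]], protected_sites=[site])
        om1 = M.branch_complexity(site, 145.0)
        om2 = M.branch_complexity(M.remap_site(site, m2), 145.0)
        assert om2 < om1

    def test_empty_cut_is_identity(self, cell0):
        m2 = M.cut_subtrees(cell0.morphology, [])
        assert m2.n_nodes() == cell0.morphology.n_nodes()
        om1 = M.branch_complexity(cell0.site_high, 145.0)
        om2 = M.branch_complexity(M.remap_site(cell0.site_high, m2), 145.0)
        assert om1 == pytest.approx(om2)

    def test_refuses_to_cut_protected_path(self, cell0):
        site = cell0.site_high
        on_path = cell0.morphology.path_to_root(site.edge_id)[1]
        with pytest.raises(ValueError, match="refusing"):
            M.cut_subtrees(cell0.morphology, [on_path], protected_sites=[site])


# ---------------------------------------------------------------------------
# Pair matching
# ---------------------------------------------------------------------------

def y_tree(d_a=145.0, d_b=131.0):
    """Trunk of 50 um then two straight daughters reaching d_a/d_b + slack."""
    nodes = [M.Node(1, None, (0, 0, 0), 0.5, "dendrite"),
             M.Node(2, 1, (0, 50, 0), 0.5, "dendrite")]
    nid = 3
    ends = []
    for sign, depth in ((1, d_a + 40), (-1, d_b + 40)):
        prev, y = 2, 50.0
        while y < depth:
            y += 20.0
            nodes.append(M.Node(nid, prev, (sign * (y - 50) / 2, y, 0), 0.5, "dendrite"))
            prev = nid
            nid += 1
        ends.append(prev)
    return M.Morphology(nodes), ends


class TestMatchSitePairs:
    def _site_at(self, m, end_edge, target):
        path = m.path_to_root(end_edge)[::-1]
        acc = 0.0
        for e in path:
            L = m.edge_length(e)
            if acc + L >= target:
                return M.Site(m, e, (target - acc) / L)
            acc += L
        raise AssertionError("target beyond tree")

    def test_example_pair_distances(self):
        m, ends = y_tree()
        a = self._site_at(m, ends[0], 145.0)
        b = self._site_at(m, ends[1], 131.0)
        pairs = M.match_site_pairs([a, b], [0.2, 0.02])
        assert pairs == [(0, 1)]

    def test_distance_threshold_excludes(self):
        m, ends = y_tree(160.0, 130.0)
        a = self._site_at(m, ends[0], 160.0)
        b = self._site_at(m, ends[1], 130.0)
        assert M.match_site_pairs([a, b], [0.2, 0.02]) == []

    def test_same_branch_excluded(self):
        m = straight_cable(20, step=10.0)
        a = tree_site(m, 11, 0.5)
        b = tree_site(m, 12, 0.5)
        assert M.match_site_pairs([a, b], [1.0, 0.5]) == []

    def test_matches_brute_force_enumeration(self):
        m, ends = y_tree()
        sites, ann = [], []
        rng = np.random.default_rng(0)
        for k, target in enumerate([100.0, 108.0, 140.0, 118.0, 99.0]):
            sites.append(self._site_at(m, ends[k % 2], target))
            ann.append(float(rng.random()))
        got = set(map(tuple, M.match_site_pairs(sites, ann)))
        expect = set()
        for i in range(5):
            for j in range(i + 1, 5):
                di, dj = M.site_metrics(sites[i])[0], M.site_metrics(sites[j])[0]
                same_branch = (sites[i].edge_id in m.path_to_root(sites[j].edge_id)
                               or sites[j].edge_id in m.path_to_root(sites[i].edge_id)
                               or sites[i].edge_id == sites[j].edge_id)
                if abs(di - dj) < 20.0 and not same_branch:
                    expect.add((i, j) if ann[i] >= ann[j] else (j, i))
        assert got == expect
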