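"""Vascular tree growth: invariants, determinism, target functionals, I/O."""
import numpy as np
import pytest

from fracperf.phantom_sim import (PerfusionDomain, VascularTree, generate_tree,
                                  insert_tumor)


def test_single_terminal_tree(disc_domain):
    """A one-terminal tree is a single root segment carrying the whole flow."""
    tree = generate_tree(disc_domain, 1, "length",
                         disc_domain.boundary_point(0.0), 42.0, seed=3)
    assert tree.n_segments == 1
    assert tree.root_flow == pytest.approx(42.0)
    assert tree.is_terminal[0]
    assert tree.radius[0] > 0
    tree.check_invariants()


def test_zero_terminals_rejected(disc_domain):
    with pytest.raises(ValueError):
        generate_tree(disc_domain, 0, "length",
                      disc_domain.boundary_point(0.0), 1.0, seed=0)


def test_seeded_determinism(disc_domain):
    """Identical seed and parameters reproduce the segment list exactly."""
    kw = dict(n_terminals=40, target="surface",
              root_inlet=disc_domain.boundary_point(np.pi),
              total_flow=50.0, seed=17)
    a = generate_tree(disc_domain, **kw)
    b = generate_tree(disc_domain, **kw)
    assert a.to_dict() == b.to_dict()


def test_different_seeds_differ(disc_domain):
    a = generate_tree(disc_domain, 20, "length",
                      disc_domain.boundary_point(0.0), 10.0, seed=1)
    b = generate_tree(disc_domain, 20, "length",
                      disc_domain.boundary_point(0.0), 10.0, seed=2)
    assert a.to_dict() != b.to_dict()


def test_target_functionals_ordered(disc_domain):
    """Each optimization target minimizes its own functional.

    Grown from the same terminal-location seed, the length-target tree is no
    longer than the volume-target tree, and the volume-target tree has no
    more intravascular volume than the length-target tree.
    """
    kw = dict(n_terminals=50, root_inlet=disc_domain.boundary_point(np.pi),
              total_flow=60.0, seed=23)
    t_len = generate_tree(disc_domain, target="length", **kw)
    t_vol = generate_tree(disc_domain, target="volume", **kw)
    assert t_len.total_length() <= t_vol.total_length()
    assert t_vol.total_volume() <= t_len.total_volume()


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_target_effect_across_seeds(disc_domain, seed):
    """The monotone target effect holds across independent growth seeds."""
    kw = dict(n_terminals=30, root_inlet=disc_domain.boundary_point(0.0),
              total_flow=30.0, seed=seed)
    t_len = generate_tree(disc_domain, target="length", **kw)
    t_vol = generate_tree(disc_domain, target="volume", **kw)
    assert t_len.total_length() <= t_vol.total_length()
    assert t_vol.total_volume() <= t_len.total_volume()


def test_flow_conservation_and_murray(small_tree):
    small_tree.check_invariants()
    res = small_tree.murray_residuals()
    assert res.size > 0 and np.all(res <= 1e-6)
    # equal terminal outflows
    term_flows = small_tree.flow[small_tree.is_terminal]
    np.testing.assert_allclose(term_flows, 60.0 / 50, rtol=1e-9)


def test_terminals_inside_domain(small_tree):
    assert np.all(small_tree.domain.contains(small_tree.dist[small_tree.is_terminal]))


def test_segment_records(small_tree):
    segs = small_tree.segments
    assert len(segs) == small_tree.n_segments
    roots = [s for s in segs if s.parent_id is None]
    assert len(roots) == 1 and roots[0].scale_level == 0
    for s in segs:
        assert len(s.child_ids) in (0, 2)
        assert s.flow > 0 and s.radius > 0


def test_json_roundtrip(tmp_path, small_tree):
    p = tmp_path / "tree.json"
    small_tree.save_json(p)
    back = VascularTree.load_json(p)
    assert back.to_dict() == small_tree.to_dict()
    back.check_invariants()


def test_host_segments_avoid_placeholder():
    dom = PerfusionDomain("disc-with-hole", (0, 0), 30.0, (4.0, -3.0), 8.0)
    tree = generate_tree(dom, 60, "volume", dom.boundary_point(np.pi), 50.0, seed=9)
    tree.check_invariants()
    from fracperf.phantom_sim.geometry import point_segment_distance
    d = point_segment_distance(np.array([4.0, -3.0]), tree.prox, tree.dist)
    assert np.all(d >= 8.0 - 1e-9)


class TestInsertTumor:
    def _pair(self, seed=31):
        host_dom = PerfusionDomain("disc-with-hole", (0, 0), 30.0, (5.0, 2.0), 8.0)
        tum_dom = PerfusionDomain("disc", (5.0, 2.0), 8.0)
        host = generate_tree(host_dom, 60, "volume",
                             host_dom.boundary_point(np.pi), 50.0, seed=seed)
        tumor = generate_tree(tum_dom, 25, "length",
                              tum_dom.boundary_point(0.5), 12.0, seed=seed + 1)
        return host, tumor

    def test_flow_conservation(self):
        host, tumor = self._pair()
        combined = insert_tumor(host, tumor)
        combined.check_invariants()
        assert combined.root_flow == pytest.approx(62.0)
        term_sum = combined.flow[combined.is_terminal].sum()
        assert term_sum == pytest.approx(62.0)

    def test_requires_placeholder(self):
        dom = PerfusionDomain("disc", (0, 0), 30.0)
        host = generate_tree(dom, 10, "volume", dom.boundary_point(0.0), 5.0, seed=1)
        _, tumor = self._pair()
        with pytest.raises(ValueError, match="placeholder"):
            insert_tumor(host, tumor)

    def test_rejects_mismatched_geometry(self):
        host, _ = self._pair()
        bad_dom = PerfusionDomain("disc", (5.0, 2.0), 6.0)  # wrong radius
        bad = generate_tree(bad_dom, 10, "length",
                            bad_dom.boundary_point(0.0), 5.0, seed=2)
        with pytest.raises(ValueError, match="congruent"):
            insert_tumor(host, bad)


def test_phantom_set_invariants(small_phantom_set):
    """Every combined phantom tree satisfies all segment invariants."""
    for sample in small_phantom_set:
        sample.combined.check_invariants()
        assert np.all(sample.combined.murray_residuals() <= 1e-6)
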