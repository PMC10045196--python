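"""Focus grouping, nucleus assignment and end-to-end field scoring."""

import numpy as np
import pytest

from centriodet.data import FociList, max_project
from centriodet.nuclei import NucleiLabels, filter_visible
from centriodet.scoring import assign, group_foci, score_field
from centriodet.simulate import SyntheticSpec, generate_field


def foci_of(points):
    return FociList("f", 1, points=points)


def brute_force_groups(points, pair_distance):
    """Transitive closure of the proximity relation, by repeated merging."""
    groups = [{i} for i in range(len(points))]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if any(np.hypot(*(points[i] - points[j])) <= pair_distance
                       for i in groups[a] for j in groups[b]):
                    groups[a] |= groups[b]
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(g) for g in groups}


class TestGroupFoci:
    def test_close_pair_is_one_group(self):
        assert group_foci(foci_of([(10, 10), (10, 12)])) == [[0, 1]]

    def test_exactly_three_px_grouped_jointly(self):
        assert group_foci(foci_of([(10, 10), (10, 13)])) == [[0, 1]]

    def test_distant_foci_stay_singletons(self):
        assert group_foci(foci_of([(10, 10), (10, 15)])) == [[0], [1]]

    def test_chain_closes_transitively(self):
        pts = [(0.0, 0.0), (0.0, 2.5), (0.0, 5.0)]  # A-B 2.5, B-C 2.5, A-C 5
        assert group_foci(foci_of(pts)) == [[0, 1, 2]]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_components(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 25, size=(12, 2))
        got = {frozenset(g) for g in group_foci(foci_of(pts))}
        assert got == brute_force_groups(pts, 3.0)

    def test_empty_input(self):
        assert group_foci(foci_of(np.empty((0, 2)))) == []


def two_nuclei_labels():
    grid = np.zeros((64, 64), np.int32)
    grid[10:25, 10:25] = 1
    grid[40:55, 35:60] = 2
    return NucleiLabels.from_labels(grid)


class TestAssign:
    def test_focus_inside_nucleus(self):
        labels = two_nuclei_labels()
        foci = foci_of([(45, 40)])
        scores, unassigned = assign(group_foci(foci), foci, labels)
        assert not unassigned
        by_label = {s.nucleus: s.count for s in scores}
        assert by_label == {1: 0, 2: 1}

    def test_nearest_mask_pixel_wins_against_all_pixel_oracle(self, rng):
        labels = two_nuclei_labels()
        for _ in range(20):
            p = rng.uniform(0, 63, size=2)
            foci = foci_of([p])
            scores, _ = assign(group_foci(foci), foci, labels)
            winner = next(s.nucleus for s in scores if s.count == 1)
            # oracle: distance to every pixel of each mask
            dists = {}
            for lab in (1, 2):
                coords = np.argwhere(labels.labels == lab)
                dists[lab] = np.min(np.hypot(coords[:, 0] - p[0], coords[:, 1] - p[1]))
            assert winner == min(dists, key=lambda l: (dists[l], l))

    def test_zero_count_nuclei_reported(self):
        labels = two_nuclei_labels()
        scores, _ = assign([], foci_of(np.empty((0, 2))), labels)
        assert {s.nucleus: s.count for s in scores} == {1: 0, 2: 0}

    def test_no_nuclei_leaves_groups_unassigned(self):
        labels = NucleiLabels.from_labels(np.zeros((32, 32), np.int32))
        foci = foci_of([(5, 5), (20, 20)])
        scores, unassigned = assign(group_foci(foci), foci, labels)
        assert scores == [] and len(unassigned) == 2

    def test_conservation_of_foci(self, rng):
        labels = two_nuclei_labels()
        pts = rng.uniform(0, 63, size=(15, 2))
        foci = foci_of(pts)
        groups = group_foci(foci)
        scores, unassigned = assign(groups, foci, labels, max_distance=10.0)
        assigned = sum(s.count for s in scores)
        loose = sum(len(g) for g in unassigned)
        assert assigned + loose == len(pts)

    def test_invariant_under_relabelling(self, rng):
        grid = np.zeros((64, 64), np.int32)
        grid[10:25, 10:25] = 7
        grid[40:55, 35:60] = 3
        labels = NucleiLabels.from_labels(grid)  # compacts to 1, 2
        pts = rng.uniform(0, 63, size=(10, 2))
        foci = foci_of(pts)
        counts_a = sorted(s.count for s in assign(group_foci(foci), foci, labels)[0])
        swapped = np.where(grid == 7, 300, np.where(grid == 3, 100, 0))
        labels_b = NucleiLabels.from_labels(swapped.astype(np.int32))
        counts_b = sorted(s.count for s in assign(group_foci(foci), foci, labels_b)[0])
        assert counts_a == counts_b

    def test_group_assigned_jointly(self):
        """A 3-px pair straddling two nuclei goes wholly to the nearer one."""
        labels = two_nuclei_labels()
        foci = foci_of([(30.0, 30.0), (30.0, 33.0)])
        scores, _ = assign(group_foci(foci), foci, labels)
        counts = sorted(s.count for s in scores)
        assert counts == [0, 2]


class TestScoreField:
    def test_blank_field_scores_all_zero(self, mini_model):
        spec = SyntheticSpec(side=256, n_nuclei=3, foci_per_nucleus=0, seed=21)
        field, _, truth = generate_field(spec)
        proj = max_project(field)
        labels = filter_visible(truth)
        scores, foci, _ = score_field(proj.planes[1], mini_model, labels,
                                      field=field.name)
        assert all(s.count == 0 for s in scores)

    def test_determinism(self, mini_model):
        spec = SyntheticSpec(side=256, n_nuclei=3, foci_per_nucleus=2, seed=22)
        field, _, truth = generate_field(spec)
        plane = max_project(field).planes[1]
        labels = filter_visible(truth)
        a = score_field(plane, mini_model, labels)[0]
        b = score_field(plane, mini_model, labels)[0]
        assert [(s.nucleus, s.count) for s in a] == [(s.nucleus, s.count) for s in b]

    def test_planted_pairs_recovered_per_nucleus(self, benchmark):
        model, _ = benchmark
        spec = SyntheticSpec(side=256, n_nuclei=3, foci_per_nucleus=2, seed=23)
        field, foci_truth, truth, planted = generate_field(spec, return_counts=True)
        plane = max_project(field).planes[1]
        scores, foci, _ = score_field(plane, model, truth)
        got = {s.nucleus: s.count for s in scores}
        hits = sum(got[lab] == planted[lab] for lab in planted)
        assert hits >= len(planted) - 1
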