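import numpy as np
import pytest

from helpers import auroc_oracle, average_precision_oracle
from paragrid import regions_eval as re_
from paragrid.structio import BindingLabels, ResidueId


def _chain(n=130, chain="H", ctype="heavy", start=1):
    rids = [ResidueId(chain, i, "", "GLY") for i in range(start, start + n)]
    positions = list(range(start, start + n))
    return re_.RegionMask.from_positions(rids, positions, ctype)


class TestRegionOf:
    @pytest.mark.parametrize("pos,region", [
        (1, "FR1"), (26, "FR1"), (27, "CDR1"), (38, "CDR1"), (39, "FR2"),
        (55, "FR2"), (56, "CDR2"), (65, "CDR2"), (66, "FR3"), (104, "FR3"),
        (105, "CDR3"), (117, "CDR3"), (118, "FR4"), (128, "FR4"),
        (129, "constant"), (130, "constant"),
    ])
    def test_boundaries(self, pos, region):
        assert re_.region_of(pos) == region

    def test_position_below_one_rejected(self):
        with pytest.raises(ValueError):
            re_.region_of(0)


class TestRegionMask:
    def test_validator_rejects_decreasing_positions(self):
        rids = [ResidueId("H", i, "", "GLY") for i in (1, 2, 3)]
        with pytest.raises(ValueError):
            re_.RegionMask.from_positions(rids, [5, 4, 6], "heavy")

    def test_validator_rejects_bad_chain_type(self):
        with pytest.raises(ValueError):
            re_.RegionMask(entries=[], chain_type="kappa")

    def test_fv_is_positions_up_to_128(self):
        mask = _chain(130)
        assert len(mask.fv_residues()) == 128


class TestCdrPm2:
    def test_contiguous_numbering_extends_by_two(self):
        mask = _chain(130)
        sel = re_.cdr_pm2_mask(mask)
        nums = {r.number for r in sel}
        for lo, hi in ((27, 38), (56, 65), (105, 117)):
            assert set(range(lo - 2, hi + 3)) <= nums
        assert 24 not in nums and 41 not in nums

    def test_truncated_at_chain_start(self):
        # chain begins inside CDR1 territory: only available flanks included
        rids = [ResidueId("H", i, "", "GLY") for i in range(27, 50)]
        mask = re_.RegionMask.from_positions(rids, list(range(27, 50)), "heavy")
        sel = re_.cdr_pm2_mask(mask)
        nums = {r.number for r in sel}
        assert min(nums) == 27

    def test_flanking_follows_sequence_not_numbering(self):
        # numbering jumps straight from 20 to 27: the two residues before
        # the loop in sequence order are 19 and 20
        positions = [18, 19, 20, 27, 28, 38, 39, 40, 41]
        rids = [ResidueId("H", p, "", "GLY") for p in positions]
        mask = re_.RegionMask.from_positions(rids, positions, "heavy")
        nums = {r.number for r in re_.cdr_pm2_mask(mask)}
        assert nums == {19, 20, 27, 28, 38, 39, 40}

    def test_superset_of_cdr(self):
        mask = _chain(130)
        cdr = set(re_.scope_residues([mask], "CDR"))
        assert cdr <= re_.cdr_pm2_mask(mask)


class TestScopes:
    def test_monotone_nesting(self):
        masks = [_chain(130, "H", "heavy"), _chain(120, "L", "light")]
        cdr = set(re_.scope_residues(masks, "CDR"))
        pm2 = set(re_.scope_residues(masks, "CDR+-2"))
        fv = set(re_.scope_residues(masks, "Fv"))
        fab = set(re_.scope_residues(masks, "Fab"))
        assert cdr < pm2 < fv < fab

    def test_single_region_scope(self):
        mask = _chain(130)
        cdr3 = re_.scope_residues([mask], "CDR3")
        assert sorted(r.number for r in cdr3) == list(range(105, 118))


def _complex_fixture(rng, n=60, chain="H"):
    mask = _chain(n, chain)
    scores = {r: float(rng.random()) for r in mask.residues()}
    labels = {r: bool(rng.random() < 0.3) for r in mask.residues()}
    return scores, labels, [mask]


class TestEvaluate:
    def test_perfect_separation(self):
        mask = _chain(40)
        rids = mask.residues()
        labels = {r: r.number <= 20 for r in rids}
        scores = {r: 0.9 if labels[r] else 0.1 for r in rids}
        rep = re_.evaluate(scores, labels, [mask], scope="Fab", threshold=0.5)
        assert rep.auc_roc == 1.0
        assert rep.auc_pr == 1.0
        assert rep.f1 == 1.0 and rep.mcc == 1.0

    def test_hand_counted_auroc(self):
        # positives score {0.9, 0.3}, negatives {0.8, 0.2}: concordant
        # pairs (0.9,0.8), (0.9,0.2), (0.3,0.2); discordant (0.3,0.8)
        mask = _chain(4)
        rids = mask.residues()
        labels = dict(zip(rids, [True, False, True, False]))
        scores = dict(zip(rids, [0.9, 0.8, 0.3, 0.2]))
        rep = re_.evaluate(scores, labels, [mask], scope="Fab")
        assert rep.auc_roc == pytest.approx(3 / 4)
        assert rep.auc_roc == pytest.approx(
            auroc_oracle(np.array([1, 0, 1, 0]), np.array([0.9, 0.8, 0.3, 0.2])))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracles_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        mask = _chain(30)
        rids = mask.residues()
        # quantized scores force ties
        scores = {r: float(np.round(rng.random(), 1)) for r in rids}
        labels = {r: bool(rng.random() < 0.4) for r in rids}
        if len({labels[r] for r in rids}) < 2:
            pytest.skip("degenerate draw")
        rep = re_.evaluate(scores, labels, [mask], scope="Fab")
        y = np.array([int(labels[r]) for r in rids])
        s = np.array([scores[r] for r in rids])
        assert rep.auc_roc == pytest.approx(auroc_oracle(y, s))
        assert rep.auc_pr == pytest.approx(average_precision_oracle(y, s))

    def test_cauroc_is_median_of_per_complex_aurocs(self):
        rng = np.random.default_rng(7)
        complexes = [_complex_fixture(rng, chain=c)
                     for c in "ABCDEFG"]
        rep = re_.evaluate_complexes(complexes, scope="Fab")
        per = []
        for scores, labels, masks in complexes:
            y = np.array([int(labels[r]) for r in masks[0].residues()])
            s = np.array([scores[r] for r in masks[0].residues()])
            per.append(auroc_oracle(y, s))
        assert rep.cauroc == pytest.approx(float(np.median(per)))
        assert rep.n_complexes == 7

    def test_single_class_complex_excluded_from_cauroc(self):
        rng = np.random.default_rng(8)
        good = _complex_fixture(rng, chain="A")
        mask = _chain(20, "B")
        allneg = ({r: float(rng.random()) for r in mask.residues()},
                  {r: False for r in mask.residues()}, [mask])
        with pytest.warns(UserWarning, match="single-class"):
            rep = re_.evaluate_complexes([good, allneg], scope="Fab")
        y = np.array([int(good[1][r]) for r in good[2][0].residues()])
        s = np.array([good[0][r] for r in good[2][0].residues()])
        assert rep.cauroc == pytest.approx(auroc_oracle(y, s))
        # the single-class complex still contributes to pooled counts
        assert rep.n_residues == 80

    def test_fab_restricted_to_fv_equals_direct_fv(self):
        rng = np.random.default_rng(9)
        scores, labels, masks = _complex_fixture(rng, n=130)
        direct = re_.evaluate(scores, labels, masks, scope="Fv")
        fv_set = set(re_.scope_residues(masks, "Fv"))
        restricted_scores = {r: s for r, s in scores.items() if r in fv_set}
        restricted = re_.evaluate(restricted_scores, labels, masks, scope="Fab")
        assert direct.auc_roc == pytest.approx(restricted.auc_roc)
        assert direct.f1 == pytest.approx(restricted.f1)
        assert direct.mcc == pytest.approx(restricted.mcc)

    def test_random_scores_give_near_zero_mcc(self):
        rng = np.random.default_rng(10)
        n = 10_000
        rids = [ResidueId("H", i, "", "GLY") for i in range(1, n + 1)]
        mask = re_.RegionMask.from_positions(rids, list(range(1, n + 1)), "heavy")
        labels = {r: bool(i % 2) for i, r in enumerate(rids)}
        scores = {r: float(rng.random()) for r in rids}
        rep = re_.evaluate(scores, labels, [mask], scope="Fab")
        assert abs(rep.mcc) < 0.03

    def test_rates_within_bounds(self):
        rng = np.random.default_rng(11)
        rep = re_.evaluate_complexes([_complex_fixture(rng)], scope="Fab",
                                     threshold=0.734)
        for v in (rep.accuracy, rep.precision, rep.recall, rep.npv, rep.spc,
                  rep.fpr, rep.f1):
            assert 0.0 <= v <= 1.0
        assert -1.0 <= rep.mcc <= 1.0


class TestPositionalBaseline:
    def test_proportion_definition(self):
        masks = [_chain(10, c) for c in "ABCD"]
        train = []
        for i, mask in enumerate(masks):
            labels = {r: (r.number == 3 and i < 3) for r in mask.residues()}
            train.append((mask, BindingLabels(labels)))
        base = re_.positional_baseline(train)
        assert base.score("heavy", 3) == pytest.approx(0.75)  # 3 of 4
        assert base.score("heavy", 5) == 0.0
        assert base.score("heavy", 999) == 0.0  # never seen

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            re_.positional_baseline([])

    def test_recovers_planted_profile_exactly(self):
        # plant binding at position p in exactly k(p) of 50 complexes
        n_complex, n_res = 50, 30
        planted = {p: (3 * p) % (n_complex + 1) for p in range(1, n_res + 1)}
        train = []
        for c in range(n_complex):
            mask = _chain(n_res, chain=f"H{c}")
            labels = {r: c < planted[r.number] for r in mask.residues()}
            train.append((mask, labels))
        base = re_.positional_baseline(train)
        for p, k in planted.items():
            assert base.score("heavy", p) == pytest.approx(k / n_complex)

    def test_predict_maps_positions(self):
        mask = _chain(5)
        base = re_.PositionalBaseline({("heavy", 2): 0.4})
        scores = base.predict(mask)
        assert scores[mask.residues()[1]] == pytest.approx(0.4)
        assert scores[mask.residues()[0]] == 0.0
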