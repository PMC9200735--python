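import numpy as np
import pytest

from baymix.populations import (
    BevertonHoltParams,
    LifeHistory,
    MigrationRule,
    PopulationState,
    RecruitmentSeries,
    SeasonalAccessibilitySchedule,
    age_sole,
    apply_natural_mortality,
    hake_initial_allocation,
    hake_migrations,
    nephrops_moult,
    recruit_hake,
    recruit_sole,
    spawning_stock_biomass,
)
from baymix.structures import (
    SEX_FEMALE,
    build_transition_matrix,
    hake_structure,
    nephrops_structure,
    sole_structure,
)


def _hake_life(structure):
    mat = (structure.midpoints > 35).astype(float)
    return LifeHistory(M=0.5, maturity=mat, weight=7e-6 * structure.midpoints**3)


class TestNaturalMortality:
    def test_zero_rate_is_identity(self):
        st = PopulationState(("z",), np.array([[100.0, 50.0]]))
        out = apply_natural_mortality(st, 0.0, 6)
        assert np.array_equal(out.abundance, st.abundance)

    def test_annual_closed_form(self):
        st = PopulationState(("z",), np.array([[1000.0]]))
        out = apply_natural_mortality(st, 0.5, 12)
        assert out.abundance[0, 0] == pytest.approx(1000.0 * np.exp(-0.5), abs=1e-9)

    def test_monthly_applications_compose_exponentially(self):
        st = PopulationState(("z",), np.array([[1000.0, 5.0]]))
        twelve = st
        for _ in range(12):
            twelve = apply_natural_mortality(twelve, 0.5, 1)
        once = apply_natural_mortality(st, 0.5, 12)
        assert np.allclose(twelve.abundance, once.abundance, rtol=1e-12)

    def test_higher_m_means_fewer_survivors(self):
        st = PopulationState(("z",), np.array([[1000.0]]))
        lo = apply_natural_mortality(st, 0.2, 12).total()
        hi = apply_natural_mortality(st, 0.8, 12).total()
        assert hi < lo


class TestHakeMigrations:
    zones = ("recruitment", "interim", "spawning", "presence")

    def _state(self, structure, fill=0.0):
        return PopulationState(self.zones, np.full((4, structure.n_classes), fill))

    def test_no_trigger_month_is_identity(self):
        hk = hake_structure()
        rules = [MigrationRule((1,), "interim", {"spawning": 1.0}, mature_only=True)]
        st = self._state(hk, 10.0)
        out = hake_migrations(st, 6, rules, hk, _hake_life(hk))
        assert np.array_equal(out.abundance, st.abundance)

    def test_january_aggregation_moves_mature_fish(self):
        hk = hake_structure()
        life = _hake_life(hk)
        st = self._state(hk)
        j60 = int(np.flatnonzero(hk.lower == 60.0)[0])
        st.abundance[1, j60] = 100.0  # interim zone, 60 cm, fully mature
        rules = [MigrationRule((1,), "interim", {"spawning": 1.0}, mature_only=True)]
        out = hake_migrations(st, 1, rules, hk, life)
        assert out.abundance[2, j60] == pytest.approx(100.0)
        assert out.abundance[1, j60] == pytest.approx(0.0)

    def test_per_class_totals_conserved_every_month(self):
        hk = hake_structure()
        life = _hake_life(hk)
        rng = np.random.default_rng(7)
        st = PopulationState(self.zones, rng.uniform(0, 50, (4, hk.n_classes)))
        rules = [
            MigrationRule((1,), "interim", {"spawning": 1.0}, mature_only=True),
            MigrationRule((4, 7), "spawning", {"interim": 0.5, "presence": 0.5}),
            MigrationRule(tuple(range(1, 13)), "recruitment", {"interim": 1.0}, min_length=20.0),
        ]
        for month in range(1, 13):
            out = hake_migrations(st, month, rules, hk, life)
            assert np.allclose(out.abundance.sum(axis=0), st.abundance.sum(axis=0))

    def test_unknown_zone_raises(self):
        hk = hake_structure()
        st = self._state(hk, 1.0)
        rules = [MigrationRule((1,), "interim", {"atlantis": 1.0})]
        with pytest.raises(KeyError, match="atlantis"):
            hake_migrations(st, 1, rules, hk)


class TestInitialAllocation:
    def test_allocation_rule(self):
        hk = hake_structure()
        life = _hake_life(hk)
        n = np.zeros(hk.n_classes)
        j15 = int(np.flatnonzero(hk.lower == 15.0)[0])
        j60 = int(np.flatnonzero(hk.lower == 60.0)[0])
        n[j15], n[j60] = 50.0, 100.0
        maturity = life.maturity.copy()
        maturity[j60] = 0.9
        life = LifeHistory(life.M, maturity, life.weight)
        st = hake_initial_allocation(
            n, life, hk, ("recruitment", "interim", "spawning", "presence")
        )
        assert st.abundance[0, j15] == 50.0  # under 20 cm -> recruitment area
        assert st.abundance[2, j60] == pytest.approx(90.0)  # mature -> spawning
        assert st.abundance[1, j60] == pytest.approx(10.0)  # rest -> interim
        assert st.abundance[3].sum() == 0.0  # presence area starts empty


class TestRecruitment:
    def test_hake_october_adds_nothing(self):
        hk = hake_structure()
        st = PopulationState(("recruitment",), np.zeros((1, hk.n_classes)))
        series = RecruitmentSeries({(2010, m): 100.0 for m in range(1, 10)})
        out = recruit_hake(st, 2010, 10, series)
        assert out.abundance.sum() == 0.0
        out = recruit_hake(st, 2010, 3, series)
        assert out.abundance[0, 0] == 100.0

    def test_negative_recruitment_rejected(self):
        with pytest.raises(ValueError):
            RecruitmentSeries({(2010, 1): -5.0})

    @pytest.mark.parametrize(
        "ssb, expected", [(0.0, 0.0), (500.0, 500.0), (1e12, pytest.approx(1000.0, rel=1e-3))]
    )
    def test_beverton_holt_closed_form(self, ssb, expected):
        bh = BevertonHoltParams(alpha=1000.0, beta=500.0)
        assert bh.recruits(ssb) == expected

    def test_sole_ageing_shifts_and_accumulates_plus_group(self):
        so = sole_structure()
        st = PopulationState(("z",), np.array([[100.0, 80, 60, 40, 20, 10, 5]]))
        out = age_sole(st)
        assert np.allclose(out.abundance[0], [0, 100, 80, 60, 40, 20, 15])
        out = recruit_sole(out, 2011, RecruitmentSeries({(2011, 1): 200.0}))
        assert out.abundance[0, 0] == 200.0


class TestNephropsMoult:
    def _setup(self):
        ne = nephrops_structure()
        g = np.where(ne.plus_group | (np.asarray(ne.sex) == "R"), 0.0, 2.0)
        T = build_transition_matrix(g, ne)
        mat = np.where(np.asarray(ne.sex) == SEX_FEMALE, 1.0, 0.0)
        life = LifeHistory(0.3, mat, np.full(ne.n_classes, 0.03))
        return ne, T, life

    def test_march_is_identity(self):
        ne, T, life = self._setup()
        st = PopulationState(("mudbank",), np.full((1, ne.n_classes), 10.0))
        out = nephrops_moult(st, 3, T, ne, life)
        assert out is st

    def test_april_advances_both_sexes(self):
        ne, T, life = self._setup()
        st = PopulationState(("mudbank",), np.zeros((1, ne.n_classes)))
        male0 = int(np.flatnonzero(np.asarray(ne.sex) == "M")[0])
        fem0 = int(np.flatnonzero(np.asarray(ne.sex) == SEX_FEMALE)[0])
        st.abundance[0, male0] = 10.0
        st.abundance[0, fem0] = 10.0
        out = nephrops_moult(st, 4, T, ne, life)
        assert out.abundance[0, male0] < 10.0
        assert out.abundance[0, fem0] < 10.0
        assert out.total() == pytest.approx(20.0)

    def test_october_skips_fully_mature_females(self):
        ne, T, life = self._setup()  # females fully mature here
        st = PopulationState(("mudbank",), np.zeros((1, ne.n_classes)))
        male0 = int(np.flatnonzero(np.asarray(ne.sex) == "M")[0])
        fem0 = int(np.flatnonzero(np.asarray(ne.sex) == SEX_FEMALE)[0])
        st.abundance[0, male0] = 10.0
        st.abundance[0, fem0] = 10.0
        out = nephrops_moult(st, 10, T, ne, life)
        assert out.abundance[0, fem0] == pytest.approx(10.0)  # stayed put
        assert out.abundance[0, male0] < 10.0  # males moulted

    def test_recruits_enter_sexed_tracks_at_spring_moult(self):
        ne, T, life = self._setup()
        st = PopulationState(("mudbank",), np.zeros((1, ne.n_classes)))
        st.abundance[0, 0] = 100.0
        out = nephrops_moult(st, 4, T, ne, life)
        male0 = int(np.flatnonzero(np.asarray(ne.sex) == "M")[0])
        fem0 = int(np.flatnonzero(np.asarray(ne.sex) == SEX_FEMALE)[0])
        assert out.abundance[0, 0] == 0.0
        assert out.abundance[0, male0] == pytest.approx(50.0)
        assert out.abundance[0, fem0] == pytest.approx(50.0)


class TestSeasonalAccessibility:
    def test_female_spring_exceeds_burrow_months(self):
        sched = SeasonalAccessibilitySchedule()
        assert sched.multiplier(4, SEX_FEMALE) > sched.multiplier(2, SEX_FEMALE)
        assert sched.multiplier(10, SEX_FEMALE) == sched.multiplier(12, SEX_FEMALE)

    def test_males_constant_all_year(self):
        sched = SeasonalAccessibilitySchedule()
        assert {sched.multiplier(m, "M") for m in range(1, 13)} == {1.0}

    def test_all_multipliers_non_negative(self):
        sched = SeasonalAccessibilitySchedule(female_burrow=0.0, female_emerged=2.0)
        assert min(sched.multiplier(m, s) for m in range(1, 13) for s in ("M", "F")) >= 0

    def test_ordering_constraint_enforced(self):
        with pytest.raises(ValueError):
            SeasonalAccessibilitySchedule(female_burrow=1.5, female_emerged=0.5)


class TestSSB:
    def test_arithmetic(self):
        st = PopulationState(("z",), np.array([[1000.0]]))
        life = LifeHistory(0.0, np.array([1.0]), np.array([0.1]))
        total, _ = spawning_stock_biomass(st, life)
        assert total == pytest.approx(0.1)  # 1000 * 1 * 0.1 kg = 0.1 t

    def test_zero_cases(self):
        life = LifeHistory(0.0, np.array([0.0]), np.array([0.1]))
        st = PopulationState(("z",), np.array([[1000.0]]))
        assert spawning_stock_biomass(st, life)[0] == 0.0

    def test_per_rectangle_split_follows_weights(self):
        st = PopulationState(("z",), np.array([[1000.0]]))
        life = LifeHistory(0.0, np.array([1.0]), np.array([1.0]))
        total, per_rect = spawning_stock_biomass(
            st, life, {"z": {"24E2": 3.0, "24E3": 1.0}}
        )
        assert per_rect["24E2"] == pytest.approx(0.75 * total)
        assert sum(per_rect.values()) == pytest.approx(total)


def test_unfished_sole_cohort_decays_exponentially():
    """With no fishing, the age-structured stock follows N(t) = N0 exp(-M t)."""
    st = PopulationState(("z",), np.array([[1000.0, 500.0, 100.0]]))
    M = 0.1
    out = st
    for _ in range(36):
        out = apply_natural_mortality(out, M, 1)
    assert np.allclose(out.abundance, st.abundance * np.exp(-M * 3.0), rtol=1e-12)
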