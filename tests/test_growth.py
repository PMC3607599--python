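import dataclasses
import math

import numpy as np
import pytest

from sporetrace.detect import SporeMarker, detect_spores
from sporetrace.germination import GerminationEvent, detect_germination, extract_trace
from sporetrace.growth import (
    AreaTrace,
    DivisionEvent,
    detect_burst,
    detect_first_division,
    outgrowth_time,
    track_all_areas,
)
from sporetrace.simulate import (
    GroundTruthManifest,
    SporeScript,
    footprint_mask,
    scripted_area_px2,
    simulate_movie,
)
from sporetrace.stack_io import RunConfig


@pytest.fixture(scope="module")
def colliding_pair():
    """Two vegetative colonies scripted to grow into each other."""
    scripts = [
        SporeScript(0, (60.0, 60.0), "vegetative", t_first_division_min=20.0,
                    generation_time_min=30.0),
        SporeScript(1, (60.0, 120.0), "vegetative", t_first_division_min=25.0,
                    generation_time_min=30.0),
    ]
    man = GroundTruthManifest(scripts=scripts, frame_interval_s=60.0, noise_sd=0.0)
    stack = simulate_movie(man, n_frames=200, shape=(120, 200), seed=0)
    return man, stack


def _scripted_first_contact_min(man, stack, margin=0):
    """Oracle: first frame time at which the scripted footprints, one dilated
    by ``margin``, overlap — computed from the manifest geometry alone."""
    from scipy.ndimage import binary_dilation
    from skimage.morphology import disk as disk_se

    shape = stack.shape
    for t in stack.times_min:
        masks = []
        for sc in man.scripts:
            area = scripted_area_px2(sc, t)
            divided = t >= sc.t_first_division_min
            masks.append(footprint_mask(shape, *sc.centroid, area, divided))
        a = masks[0]
        if margin:
            a = binary_dilation(a, structure=disk_se(margin))
        if np.any(a & masks[1]):
            return float(t)
    return None


class TestTrackArea:
    def test_areas_follow_scripted_exponential_law(self, colliding_pair, explicit_config):
        man, stack = colliding_pair
        markers = [
            SporeMarker(s.spore_id, s.centroid, 28, 40.0) for s in man.scripts
        ]
        traces = track_all_areas(stack, markers, explicit_config)
        tr = traces[0]
        sc = man.scripts[0]
        for t, a in zip(tr.times_min[::20], tr.areas_px2[::20]):
            expected = scripted_area_px2(sc, t)
            bound = 4.0 * math.sqrt(math.pi * expected) + 4.0
            assert abs(a - expected) <= bound

    def test_colliding_colonies_both_censored(self, colliding_pair, explicit_config):
        man, stack = colliding_pair
        markers = [SporeMarker(s.spore_id, s.centroid, 28, 40.0) for s in man.scripts]
        traces = track_all_areas(stack, markers, explicit_config)
        t_contact = _scripted_first_contact_min(man, stack)
        assert t_contact is not None
        for sid in (0, 1):
            assert traces[sid].censor_reason == "touch_colony"
            assert traces[sid].censored_at_min <= t_contact
            # censoring happens because of the margin, not long before contact
            assert traces[sid].censored_at_min >= t_contact - 30.0

    def test_censoring_monotone_in_collision_margin(self, colliding_pair):
        """A larger collision margin can only censor earlier, never later."""
        man, stack = colliding_pair
        markers = [SporeMarker(s.spore_id, s.centroid, 28, 40.0) for s in man.scripts]
        censored = []
        for margin in (0, 2, 5):
            cfg = RunConfig(bright_threshold=140.0, dark_threshold=70.0,
                            collision_margin_px=margin)
            tr = track_all_areas(stack, markers, cfg)[0]
            censored.append(tr.censored_at_min)
        assert censored[0] >= censored[1] >= censored[2]

    def test_area_additive_over_disjoint_colonies(self, colliding_pair, explicit_config):
        """While uncensored, the summed per-colony areas equal the total
        above-background area of the frame."""
        man, stack = colliding_pair
        markers = [SporeMarker(s.spore_id, s.centroid, 28, 40.0) for s in man.scripts]
        traces = track_all_areas(stack, markers, explicit_config)
        t_stop = min(tr.times_min[-1] for tr in traces.values())
        for k in (0, 40, 80):
            t = stack.times_min[k]
            if t > t_stop:
                break
            total = int(np.sum(np.abs(stack.frames[k] - 100.0) > 20.0))
            per_colony = sum(
                tr.areas_px2[np.searchsorted(tr.times_min, t)]
                for tr in traces.values()
            )
            assert total == per_colony

    def test_dormant_spore_runs_to_end_of_movie(self, three_fate_stack, config):
        markers = detect_spores(three_fate_stack, config)
        dormant = [m for m in markers if abs(m.centroid[0] - 90) < 2][0]
        tr = track_all_areas(three_fate_stack, markers, config)[dormant.spore_id]
        assert tr.censor_reason == "end_of_movie"
        assert tr.censored_at_min is None
        assert np.ptp(tr.areas_px2) <= 2  # near-constant small area

    def test_no_values_recorded_after_censoring(self, colliding_pair, explicit_config):
        man, stack = colliding_pair
        markers = [SporeMarker(s.spore_id, s.centroid, 28, 40.0) for s in man.scripts]
        tr = track_all_areas(stack, markers, explicit_config)[0]
        assert tr.times_min[-1] < tr.censored_at_min


@pytest.fixture(scope="module")
def outgrowth_movie():
    """One spore with a realistic outgrowth time: germination ends at
    9 min, first division 254 min later."""
    sc = SporeScript(
        0, (60.0, 60.0), "outgrow",
        t_germ_start_min=5.0, germ_duration_min=4.0,
        t_first_division_min=263.0, generation_time_min=62.0,
    )
    man = GroundTruthManifest(scripts=[sc], frame_interval_s=60.0, noise_sd=0.0)
    return man, simulate_movie(man, n_frames=310, shape=(120, 120), seed=0)


class TestFirstDivision:
    def test_division_detected_within_two_frames(self, outgrowth_movie, explicit_config):
        man, stack = outgrowth_movie
        markers = detect_spores(stack, explicit_config)
        tr = track_all_areas(stack, markers, explicit_config)[0]
        div = detect_first_division(stack, tr, markers[0], explicit_config)
        assert div is not None and div.source == "auto"
        assert div.t_division_min == pytest.approx(263.0, abs=2.0)

    def test_outgrowth_time_recovered(self, outgrowth_movie, explicit_config):
        man, stack = outgrowth_movie
        markers = detect_spores(stack, explicit_config)
        trace = extract_trace(stack, markers[0], explicit_config.center_radius_px)
        event = detect_germination(trace, explicit_config)
        tr = track_all_areas(stack, markers, explicit_config)[0]
        div = detect_first_division(stack, tr, markers[0], explicit_config)
        out = outgrowth_time(event, div)
        assert out == pytest.approx(254.0, abs=2.0)

    def test_germinate_only_spore_never_divides(self, three_fate_stack, config):
        markers = detect_spores(three_fate_stack, config)
        germ_only = [m for m in markers if abs(m.centroid[1] - 90) < 2][0]
        tr = track_all_areas(three_fate_stack, markers, config)[germ_only.spore_id]
        assert detect_first_division(three_fate_stack, tr, germ_only, config) is None

    def test_manual_override_returned_verbatim(self, three_fate_stack, config):
        markers = detect_spores(three_fate_stack, config)
        tr = track_all_areas(three_fate_stack, markers, config)[markers[0].spore_id]
        div = detect_first_division(
            three_fate_stack, tr, markers[0], config, manual_t_division_min=100.0
        )
        assert div == DivisionEvent(markers[0].spore_id, 100.0, "manual")


def _area_trace(times, areas):
    return AreaTrace(
        spore_id=0, times_min=np.asarray(times, float),
        areas_px2=np.asarray(areas, float), pixel_size_um=0.065,
        censored_at_min=None, censor_reason="end_of_movie",
    )


def _germ_event(t_start=10.0, t_end=14.0):
    return GerminationEvent(
        spore_id=0, detected=True, i_pre=180.0, i_post=40.0, drop_range=140.0,
        t_start_min=t_start, t_end_min=t_end, duration_min=t_end - t_start,
    )


class TestBurst:
    def test_scripted_forty_percent_jump_found(self, explicit_config):
        t = np.arange(0.0, 60.0, 1.0)
        a = np.full_like(t, 30.0)
        a[t >= 30.0] *= 1.4  # single-frame 40% jump at t=30
        ev = detect_burst(
            _area_trace(t, a), _germ_event(), DivisionEvent(0, 55.0, "auto"),
            explicit_config,
        )
        assert len(ev) == 1
        assert ev[0].t_burst_min == 30.0
        assert ev[0].relative_jump == pytest.approx(0.4)

    def test_smooth_exponential_growth_has_no_burst(self, explicit_config):
        t = np.arange(0.0, 120.0, 1.0)
        a = 30.0 * 2 ** (t / 40.0)
        ev = detect_burst(
            _area_trace(t, a), _germ_event(), DivisionEvent(0, 110.0, "auto"),
            explicit_config,
        )
        assert ev == []

    def test_jump_before_end_of_germination_not_reported(self, explicit_config):
        t = np.arange(0.0, 60.0, 1.0)
        a = np.full_like(t, 30.0)
        a[t >= 8.0] *= 1.4  # jump while still germinating (t_end = 14)
        ev = detect_burst(
            _area_trace(t, a), _germ_event(), DivisionEvent(0, 55.0, "auto"),
            explicit_config,
        )
        assert ev == []


class TestOutgrowthTime:
    def test_definition_is_division_minus_end_of_germination(self):
        ev = _germ_event(t_start=46.5, t_end=50.0)
        div = DivisionEvent(0, 304.0, "manual")
        assert outgrowth_time(ev, div) == pytest.approx(254.0)

    def test_absent_when_division_missing(self):
        assert outgrowth_time(_germ_event(), None) is None
        assert outgrowth_time(None, DivisionEvent(0, 100.0, "auto")) is None

    def test_inconsistent_annotation_raises(self):
        ev = _germ_event(t_start=46.5, t_end=50.0)
        with pytest.raises(ValueError, match="precedes"):
            outgrowth_time(ev, DivisionEvent(0, 40.0, "manual"))
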