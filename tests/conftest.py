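import numpy as np
import pytest

from batforage import arrayloc, biologging, synthio


@pytest.fixture(scope="session")
def geometry():
    return arrayloc.MicArrayGeometry.y_array(1.0)


@pytest.fixture(scope="session")
def session7():
    """One full synthetic logging session, shared across tests (read-only)."""
    return synthio.simulate_logging_session(seed=7)


@pytest.fixture(scope="session")
def geotrack7(session7):
    track, attacks = biologging.build_geotrack(
        session7["fixes"], session7["events"],
        session7["dem"], session7["habitat_grid"])
    return track, attacks


@pytest.fixture(scope="session")
def short_recording():
    """Close-range rendered foraging bout: (audio, fs, schedule, truth, scene)."""
    flight = synthio.FlightSim(waypoints=[[-15, -5, 12], [15, 8, 16]], speed_ms=8.0)
    traj = synthio.simulate_flight(flight, dt=0.05)
    sched = synthio.make_call_schedule(3.8, seed=3, n_attacks=1)
    sched = sched[sched.time_s < traj.time_s.iloc[-1]].reset_index(drop=True)
    scene = synthio.SceneConfig(sample_rate=250_000, noise_db=-60)
    audio, truth = synthio.render_array_audio(traj, sched, scene, seed=0)
    return audio.astype(float), scene.sample_rate, sched, truth, scene


def random_sources(n, seed, r_lo=5.0, r_hi=46.0):
    """Random upper-half-space sources within the validity radius."""
    rng = np.random.default_rng(seed)
    r = rng.uniform(r_lo, r_hi, n)
    az = rng.uniform(0, 2 * np.pi, n)
    el = rng.uniform(np.radians(5), np.radians(80), n)
    return np.stack([r * np.cos(el) * np.cos(az),
                     r * np.cos(el) * np.sin(az),
                     r * np.sin(el)], axis=1)
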