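import numpy as np
import pytest

from mgsalloc import IndividualRecord, StudyConfig

FULL_ORGANS = dict(testis_sv_weight=80.0, penis_weight=1.0, ovary_weight=400.0)


def make_record(id, shell_id="S1", x=0.0, y=0.0, penis_length=2.5,
                operculum_weight=1000.0, **kw):
    fields = dict(FULL_ORGANS)
    fields.update(kw)
    return IndividualRecord(
        id=id, shell_id=shell_id, x=x, y=y,
        penis_length=penis_length, operculum_weight=operculum_weight, **fields
    )


@pytest.fixture
def study_config():
    return StudyConfig()


@pytest.fixture
def line_records():
    """Three barnacles on a line at x = 0, 4, 9 with reaches 4.55, 3.458, 5.46.

    Exhaustively checking the 6 ordered pairs: A reaches B (gap 4 <= 4.55)
    but not C (9 > 4.55); B reaches neither (4 > 3.458); C reaches B
    (5 <= 5.46) but not A (9 > 5.46). Edges: {A->B, C->B}.
    """
    return [
        make_record("A", x=0.0, penis_length=2.5),
        make_record("B", x=4.0, penis_length=1.9),
        make_record("C", x=9.0, penis_length=3.0),
    ]


def random_population(rng: np.random.Generator, n_shells=5, max_per_shell=10,
                      spread=8.0):
    """Small random multi-shell population for property tests."""
    records = []
    for s in range(n_shells):
        n = int(rng.integers(1, max_per_shell + 1))
        for k in range(n):
            records.append(
                make_record(
                    f"S{s}-{k}",
                    shell_id=f"S{s}",
                    x=float(rng.uniform(-spread, spread)),
                    y=float(rng.uniform(-spread, spread)),
                    penis_length=float(rng.uniform(1.67, 4.46)),
                    operculum_radius=float(rng.uniform(0, 0.8)),
                )
            )
    return records


def brute_force_degrees(records, config):
    """Independent O(n^2) re-count of out/in degrees from first principles."""
    out = {r.id: 0 for r in records}
    inn = {r.id: 0 for r in records}
    for a in records:
        for b in records:
            if a.id == b.id or a.shell_id != b.shell_id:
                continue
            d = np.hypot(a.x - b.x, a.y - b.y)
            if config.distance_mode == "operculum_edge":
                d = max(0.0, d - a.operculum_radius - b.operculum_radius)
            if d <= config.elongation_factor * a.penis_length:
                out[a.id] += 1
                inn[b.id] += 1
    return out, inn
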