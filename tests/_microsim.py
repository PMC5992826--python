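"""Individual-level Monte-Carlo oracle for the cohort engine.

Simulates N individuals through the same age-specific transition kernel the
deterministic cohort engine uses (no screening), tracking state occupancy
at cycle start and new clinical diagnoses per cycle.  Used only as an
independent statistical check: the deterministic occupancy must lie within
Monte-Carlo error of these counts.
"""

from __future__ import annotations

import numpy as np

from crcscreen.natural_history import (
    CLINICAL_STATES,
    N_INTERNAL,
    aggregate_to_public,
    build_transition_matrix,
    initial_distribution,
)


def microsim_no_screening(params, life_table, n: int = 100_000, seed: int = 0):
    """Return (occupancy_by_age, incidence) from an individual-level run.

    ``occupancy_by_age[age]`` are public-state counts at cycle start;
    ``incidence`` maps age -> (new clinical cases, living at cycle start).
    """
    rng = np.random.default_rng(seed)
    start, end = params.econ.screening_start_age, params.econ.max_age
    init = initial_distribution(params).x
    states = rng.choice(N_INTERNAL, size=n, p=init)
    clinical = np.array([int(s) for s in CLINICAL_STATES])
    dead = np.array([N_INTERNAL - 2, N_INTERNAL - 1])  # DEAD_CRC, DEAD_OTHER

    occupancy: dict[int, np.ndarray] = {}
    incidence: dict[int, tuple[int, int]] = {}
    for age in range(start, end):
        counts = np.bincount(states, minlength=N_INTERNAL).astype(float)
        occupancy[age] = aggregate_to_public(counts)
        living = int(n - counts[dead].sum())
        P = build_transition_matrix(params, age, life_table).p
        C = np.cumsum(P, axis=1)
        u = rng.random(n)
        new_states = (u[:, None] > C[states]).sum(axis=1)
        entered = np.isin(new_states, clinical) & (new_states != states)
        incidence[age] = (int(entered.sum()), living)
        states = new_states
    return occupancy, incidence
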