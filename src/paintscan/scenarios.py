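"""Canned study scenarios: the baseline admixture-with-selection setting and
the demographic-misspecification variants used to probe robustness.

Baseline: a single 50 Mb chromosome with uniform crossover probability
1.3e-8 per bp per gamete; diploid size N = 10,000 founded by a single
admixture pulse with m = 0.5; 50 generations; the beneficial allele fixed in
source 1 and absent from source 2, with h = 0.5 and s drawn uniformly from
[0, 0.5]; the selected site placed uniformly in the central 90% of the
chromosome so that the 11-pixel training target stays on-image.
"""

from __future__ import annotations

import numpy as np

from .simulate import (
    DemographicModel,
    RecombinationMap,
    SelectedSite,
    SelectionModel,
    SizeEvent,
)

CHROM_LENGTH = 50e6
CROSSOVER_RATE = 1.3e-8
BASELINE_N = 10_000
BASELINE_M = 0.5
BASELINE_GENERATIONS = 50
S_RANGE = (0.0, 0.5)
PLACEMENT_FRACTION = (0.05, 0.95)


def baseline_model(
    m: float = BASELINE_M,
    N0: int = BASELINE_N,
    generations: int = BASELINE_GENERATIONS,
    n_chromosomes: int = 1,
    length: float = CHROM_LENGTH,
    rate: float = CROSSOVER_RATE,
    size_events: tuple[SizeEvent, ...] = (),
) -> DemographicModel:
    chroms = tuple(RecombinationMap(length=length, rate=rate) for _ in range(n_chromosomes))
    return DemographicModel(m=m, N0=N0, generations=generations, chromosomes=chroms,
                            size_events=size_events)


def draw_selection(
    rng: np.random.Generator,
    model: DemographicModel,
    s: float | None = None,
    s_range: tuple[float, float] = S_RANGE,
    position: float | None = None,
    chromosome: int = 0,
    h: float = 0.5,
    p_source1: float = 1.0,
    p_source2: float = 0.0,
    placement: tuple[float, float] = PLACEMENT_FRACTION,
) -> SelectionModel:
    """Draw one selected site under the study conditions (s ~ U(0, 0.5),
    position uniform in the central 90% of the chromosome by default)."""
    L = model.chromosomes[chromosome].length
    if s is None:
        s = float(rng.uniform(*s_range))
    if position is None:
        position = float(rng.uniform(placement[0] * L, placement[1] * L))
    return SelectionModel(
        (SelectedSite(chromosome, position, s, h, p_source1, p_source2),)
    )


def neutral_selection() -> SelectionModel:
    return SelectionModel(())


def misspecification_models(base: DemographicModel | None = None) -> dict[str, DemographicModel]:
    """The robustness suite: one altered demographic feature per scenario.

    Bottlenecks reduce N at generation 25 for 10 generations then restore
    N0; the expansion (200%) and contraction (50%) happen at generation 25
    and persist.  All scenarios start at N = 10,000.
    """
    if base is None:
        base = baseline_model()
    N0 = base.N0

    def resized(events):
        return baseline_model(N0=N0, size_events=events)

    return {
        "m=0.1": baseline_model(m=0.1),
        "m=0.25": baseline_model(m=0.25),
        "m=0.75": baseline_model(m=0.75),
        "m=0.9": baseline_model(m=0.9),
        "gen=25": baseline_model(generations=25),
        "gen=100": baseline_model(generations=100),
        "bottleneck_50": resized(
            (SizeEvent(25, "bottleneck_start", N0 // 2), SizeEvent(35, "bottleneck_end"))
        ),
        "bottleneck_10": resized(
            (SizeEvent(25, "bottleneck_start", N0 // 10), SizeEvent(35, "bottleneck_end"))
        ),
        "expansion": resized((SizeEvent(25, "set_size", 2 * N0),)),
        "contraction": resized((SizeEvent(25, "set_size", N0 // 2),)),
    }


def fst0_selection(
    rng: np.random.Generator, model: DemographicModel, s: float | None = None
) -> SelectionModel:
    """Both sources carry the beneficial allele at frequency 0.5 (FST = 0 at
    the selected locus): allele-frequency change decouples from ancestry."""
    return draw_selection(rng, model, s=s, p_source1=0.5, p_source2=0.5)
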