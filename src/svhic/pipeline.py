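"""End-to-end deletion-experiment analysis: from raw maps to Z track and calls.

The analysis chain for one experiment is:

1. VC_SQRT-normalize the wild-type and mutant maps (mutant already expressed
   in reference coordinates, deletion masked).
2. Build the distance-only null V* = simulate_wt_under_deletion(wt):
   balanced liftover of the wild type into deleted-genome coordinates
   followed by easy liftover back.
3. Score D(k, f) between the observed mutant map and V*, Z-transform, and
   call insulation-change intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

from .contact_core import ContactMap, vc_sqrt_normalize
from .insulation import (
    DifferentialInsulationTrack,
    InsulationChangeCall,
    call_insulation_changes,
    d_score,
)
from .liftover import DeletionSpec, simulate_wt_under_deletion
from .simulate import ExperimentSpec, simulate_deletion_experiment

__all__ = ["DeletionAnalysis", "analyze_deletion", "run_simulated_experiment"]

DEFAULT_WINDOW_BINS = 20  # 100 kb at 5 kb resolution


@dataclass
class DeletionAnalysis:
    wt_norm: ContactMap
    mutant_norm: ContactMap
    null_prediction: ContactMap
    track: DifferentialInsulationTrack
    calls: list[InsulationChangeCall]


def analyze_deletion(
    wt_raw: ContactMap,
    mutant_in_ref_raw: ContactMap,
    deletion: DeletionSpec,
    f: int = DEFAULT_WINDOW_BINS,
    z_threshold: float = 2.0,
) -> DeletionAnalysis:
    """Score a mutant map against the distance-only prediction of its wild type."""
    wt_n = vc_sqrt_normalize(wt_raw)
    mut_n = vc_sqrt_normalize(mutant_in_ref_raw)
    null = simulate_wt_under_deletion(wt_n, deletion)
    track = d_score(mut_n, null, f=f)
    calls = call_insulation_changes(track, z_threshold=z_threshold)
    return DeletionAnalysis(
        wt_norm=wt_n,
        mutant_norm=mut_n,
        null_prediction=null,
        track=track,
        calls=calls,
    )


def run_simulated_experiment(
    spec: ExperimentSpec, f: int = DEFAULT_WINDOW_BINS, z_threshold: float = 2.0
) -> DeletionAnalysis:
    """Simulate a deletion experiment and run the full analysis on it."""
    wt, mut_ref = simulate_deletion_experiment(spec)
    return analyze_deletion(wt, mut_ref, spec.deletion, f=f, z_threshold=z_threshold)
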