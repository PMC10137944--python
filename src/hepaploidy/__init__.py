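"""Hepatic ploidy quantification from nucleus instance masks.

The package reconstructs each hepatocyte's cellular ploidy (nuclei per
cell) from the relative distance between nuclei, and each nucleus's ploidy
class (2n/4n/8n) from its cross-sectional area via a two-stage Gaussian
mixture model validated against a sphere-slicing simulation.
"""

from .areasim import (THEORETICAL_MULTIPLIER, AreaSimConfig, censor,
                      class_means, class_sigmas, count_histogram_modes,
                      search_merge_multiplier, simulate_areas)
from .distance import (CalibrationResult, ResolutionSpec, ThresholdCalibrator,
                       collect_calibration_pairs, convert_threshold,
                       relative_distance, select_threshold)
from .gmm import (EMConvergenceError, NuclearPloidyGMM, classify_nuclei,
                  fit_gmm, summarize_total_ploidy, total_ploidy_distribution)
from .grouping import (RelativeDistanceGrouping, group_nuclei,
                       summarize_cellular_ploidy)
from .pipeline import (PipelineConfig, load_instances, run_calibration,
                       run_patch)
from .records import (CellAssignment, CellRecord, NuclearPloidyCall,
                      NucleusPair, NucleusRecord)
from .segmentation import (assign_nuclei_to_cells, filter_central,
                           segment_membranes, segment_nuclei)
from .synthetic import (PatchTruth, PlacementError, SyntheticPatchSpec,
                        generate_if_patch, generate_labelled_mask)

__version__ = "0.1.0"

__all__ = [
    "AreaSimConfig", "CalibrationResult", "CellAssignment", "CellRecord",
    "EMConvergenceError", "NuclearPloidyCall", "NuclearPloidyGMM",
    "NucleusPair", "NucleusRecord", "PatchTruth", "PipelineConfig",
    "PlacementError", "RelativeDistanceGrouping", "ResolutionSpec",
    "SyntheticPatchSpec", "THEORETICAL_MULTIPLIER", "ThresholdCalibrator",
    "assign_nuclei_to_cells", "censor", "class_means", "class_sigmas",
    "classify_nuclei", "collect_calibration_pairs", "convert_threshold",
    "count_histogram_modes", "filter_central", "fit_gmm",
    "generate_if_patch", "generate_labelled_mask", "group_nuclei",
    "load_instances", "relative_distance", "run_calibration", "run_patch",
    "search_merge_multiplier", "segment_membranes", "segment_nuclei",
    "select_threshold", "simulate_areas", "summarize_cellular_ploidy",
    "summarize_total_ploidy", "total_ploidy_distribution",
]
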