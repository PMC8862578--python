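"""pediplan: CT-value-driven pedicle screw trajectory planning.

Plans pedicle screw corridors on CT volumes by maximizing the mean
Hounsfield value of the screw cylinder under anatomical safety constraints,
alongside the conventional manual baseline, axial/sagittal trajectory
measurements, a T'-score osteoporosis classifier and a synthetic vertebra
phantom with a decalcification model for validation.
"""

from .constraints import (FeasibilityReport, check_anterior_margin,
                          check_containment, check_pedicle_passage, feasible)
from .densitometry import (GroupSummary, TPrimeResult, percent_difference,
                           percent_of, reference_from_values, study_report,
                           t_prime, tprime_of_group)
from .geometry import (Line, PlacementError, Plane, Trajectory,
                       TrajectoryMeasurement, VertebralFrame, cylinder_samples,
                       mean_ct_value, measure_trajectory, placement_error,
                       reconstruct_trajectory)
from .phantom import (CorridorSpec, PhantomGroundTruth, PhantomSpec,
                      apply_decalcification, calibrate_decalcification,
                      default_corridor, generate_phantom, vertebral_mean_hu,
                      with_corridor)
from .planners import (PedicleSection, PlanResult, PlanningError,
                       SearchSettings, brute_force_plan, estimate_frame,
                       find_min_pedicle_section, plan_auto, plan_manual,
                       recommend_screw)
from .volume import (BONE_LABELS, LABEL_SCHEME, CtVolume, DistanceMap,
                     LabelVolume, VolumeError, distance_map, load_labels,
                     load_volume, sample_hu, save_volume, world_to_voxel)

__version__ = "0.1.0"


def frame_from_truth(truth: PhantomGroundTruth, side: str) -> VertebralFrame:
    """Vertebral measurement frame taken from phantom ground truth."""
    return VertebralFrame(midline_plane=truth.midline_plane,
                          lower_endplate_plane=truth.lower_endplate_plane,
                          axial_normal=truth.axial_normal, side=side)
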