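"""Trajectory-based gene-by-environment analysis of posttraumatic stress.

Latent class growth analysis of three-wave PTS scores, fit-statistic-driven
class enumeration, and classification-error-adjusted multinomial regression
of class membership on SNP genotype, childhood physical abuse, and their
interaction — with a calibrated synthetic-cohort generator so every stage
is verifiable by parameter recovery.
"""

__version__ = "0.1.0"

from .dataset import LongitudinalDataset, N_WAVES, WAVE_TIMES
from .simulate import (
    AbuseDistribution,
    CovariateParams,
    DropoutSpec,
    EffectSpec,
    SimulationSpec,
    dnhs_like_spec,
    simulate_cohort,
    simulate_cts_items,
    simulate_pcl_items,
)
from .io import read_dataset, write_dataset
from .lcga import (
    LCGAFit,
    LCGAParameters,
    assign_modal_class,
    class_density,
    e_step,
    fit_lcga,
    label_trajectories,
    m_step,
)
from .selection import (
    FitReport,
    average_posterior_probabilities,
    bic_stats,
    bootstrap_lrt,
    entropy_stat,
    enumerate_classes,
)
from .three_step import (
    ClassificationErrorMatrix,
    CovariateModelResult,
    apply_bonferroni,
    classification_error_matrix,
    fit_corrected_multinomial,
    run_interaction_model,
    run_main_effects_model,
)
from .descriptives import (
    compare_included_vs_dropped,
    cronbach_alpha,
    crosstab_by_class,
    genotype_qc,
    hwe_exact_test,
    median_split,
    score_cts,
    score_pcl,
    spearman_rge,
)
from .pipeline import RunConfig, render_trajectory_plot, run_pipeline
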