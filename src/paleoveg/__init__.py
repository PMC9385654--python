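"""paleoveg: Bayesian neural network reconstruction of paleovegetation.

A supervised classifier of vegetation type ("open" grasslands, savannas,
steppes, deserts and tundra versus "closed" forest) at arbitrary points
in space and geologic time. Features combine spatial/temporal distances
to the nearest fossil or current occurrence of each selected taxon per
geological stage with abiotic predictors (paleoclimate, elevation,
global temperature, CO2, paleocoordinates, age). Weights are sampled by
Metropolis-Hastings MCMC under standard-normal priors, giving posterior
class probabilities, calibrated uncertainty thresholds, open-habitat
fraction time series with HPD bands, and permutation feature importance.
"""

from .chrono import GeoStage, StageTable, discretize_age, load_stage_table
from .occurrences import (
    CropWindow,
    DEFAULT_WINDOW,
    assign_stages,
    crop_to_window,
    deduplicate,
    filter_informative_taxa,
    merge_sources,
    read_occurrences,
    read_vegetation_points,
)
from .projection import AlbersEqualArea, project_equal_area
from .rasters import Curve, Raster, RasterStack, interpolate_time_slices, read_ascii_grid
from .features import (
    ABIOTIC_FEATURE_NAMES,
    BioticDistanceTensor,
    FeatureMatrix,
    ModelData,
    ScalingBounds,
    apply_joint_scaling,
    apply_scaling,
    assemble_features,
    build_abiotic_matrix,
    build_distance_tensor,
    extract_abiotic,
    nearest_distance_per_stage,
    perturb_features,
    prepare_datasets,
    scale_features,
    sentinel_distance,
)
from .bnn import (
    BNNConfig,
    WeightSample,
    dense_forward,
    forward,
    layer1_forward,
    layer2_forward,
    log_likelihood,
    log_prior,
    output_probs,
    pool_taxa,
    swish,
)
from .mcmc import (
    MCMCSettings,
    PosteriorTrace,
    init_weights,
    load_trace,
    log_posterior,
    mh_step,
    resume_chain,
    run_chain,
    save_trace,
)
from .inference import (
    OpenFractionSeries,
    PredictionResult,
    calibrate_threshold,
    expansion_rate,
    habitat_association,
    hpd_interval,
    open_fraction_series,
    posterior_probs,
    predict_grid,
)
from .evaluation import (
    CVFold,
    EvaluationReport,
    ImportanceReport,
    evaluate_model,
    make_cv_folds,
    permutation_importance,
    weighted_accuracy,
)
from .synthetic import (
    SyntheticScenario,
    SyntheticTaxon,
    TruthField,
    default_taxa,
    generate_abiotic_surfaces,
    generate_bundle,
    generate_occurrences,
    generate_training_points,
    generate_truth_field,
    grid_instances,
    scenario_inputs,
)

__version__ = "0.1.0"
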