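"""Running from a YAML config file with overrides, and writing outputs.

Loads the shipped aging preset config, shrinks it to a quick 2000-step
run with snapshots, runs it, and writes metrics.csv / snapshots.csv /
manifest.json -- the same artifacts the `mitoq simulate` command-line
produces.
"""

import tempfile
from pathlib import Path

from mitoq import __version__, run_simulation
from mitoq.io import RunManifest, config_to_dict, read_config, write_manifest, write_trajectory
from mitoq.scenarios import apply_overrides

config = read_config(Path(__file__).parent / "configs" / "aging.yaml")
config = apply_overrides(config, {"n_steps": 2000, "record_every": 500,
                                  "record_snapshots": True, "seed": 11})

traj = run_simulation(config)
outdir = Path(tempfile.mkdtemp(prefix="mitoq-"))
paths = write_trajectory(traj, outdir)
manifest = RunManifest(scenario="aging", config=config_to_dict(config),
                       seed=config.seed, version=__version__,
                       nprob_final=traj.final_metrics.nprob, normalization_ok=True)
paths["manifest"] = write_manifest(manifest, outdir)

m = traj.final_metrics
print(f"after {m.t:.0f} tu: qbar={m.qbar:.3f}, sigma_q={m.sigma_q:.3f}, "
      f"P(0)={m.p0:.3f}, N_prob={m.nprob:.15f}")
for kind, path in paths.items():
    print(f"wrote {kind}: {path}")
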