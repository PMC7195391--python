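"""Shared roster and paths for the numbered analysis scripts.

The study design mirrors the lipid-screen logic at desk scale: three
unrestrained preset conditions spanning high / mid / low bent-state
prevalence plus the all-bent (dewetted-cavity) restrained condition, three
1-us replicates each.  Replicates are regenerated deterministically from
their seeds, so scripts can run independently and in any order.
"""

from pathlib import Path

from kinkgate.synthetic import preset_conduction_regime

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

PRESETS = ("high_current", "mid_current", "low_current", "all_bent_dewetted")
N_REPLICATES = 3
N_FRAMES = 10000  # 1 us per replicate at 0.1 ns/frame
BASE_SEED = 100


def replicate_specs():
    """Yield (preset_name, replicate_id, SyntheticSpec) for the whole study."""
    for p, preset in enumerate(PRESETS):
        for rep in range(N_REPLICATES):
            spec = preset_conduction_regime(preset)
            spec.n_frames = N_FRAMES
            spec.seed = BASE_SEED + 10 * p + rep
            yield preset, f"{preset}_r{rep}", spec


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
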