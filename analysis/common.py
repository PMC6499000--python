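"""Shared locations and lazy fixture generation for the analysis scripts."""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
FIXTURES = SCRATCH / "fixtures"
FIGURES = SCRATCH / "figures"
SEED = 11


def ensure_fixtures():
    """Generate the synthetic study once; reuse it across scripts."""
    from spheroquant.pipeline import FixtureConfig, generate_fixtures

    manifest = FIXTURES / "manifest.json"
    if not manifest.exists():
        generate_fixtures(FIXTURES, FixtureConfig(seed=SEED))
    return manifest


def ensure_run():
    """Run the full pipeline over the fixtures once; reuse the run directory."""
    from spheroquant.pipeline import run_pipeline

    out = SCRATCH / "run"
    if not (out / "spheroids.csv").exists():
        run = run_pipeline(ensure_fixtures(), out, seed=SEED)
        assert run.ok, run.errors
    return out


for d in (SCRATCH, RESULTS, FIGURES):
    d.mkdir(exist_ok=True)
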