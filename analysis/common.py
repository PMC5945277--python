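"""Shared paths and fixture bootstrap for the numbered analysis scripts.

Window time series live under ``scratch/`` (bulky, regenerated on demand);
summary tables go to ``results/``.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "scratch" / "fixtures"
RESULTS = ROOT / "results"

MASTER_SEED = 2026


def ensure_fixtures():
    """Generate the synthetic fixture bundle if it is not present."""
    from dimerbend import write_fixture_set

    RESULTS.mkdir(exist_ok=True)
    if not (FIXTURES / "manifest.json").exists():
        write_fixture_set(FIXTURES, master_seed=MASTER_SEED)
    return FIXTURES
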