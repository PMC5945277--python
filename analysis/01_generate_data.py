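"""Generate the synthetic study data: two planted Gaussian ensembles, a
hinge-dimer ensemble with two anchor states, and umbrella windows on a 5 kT
quartic double well.  Everything is seeded, so reruns are byte-identical."""

import json

from common import FIXTURES, MASTER_SEED, RESULTS, ensure_fixtures


def main():
    FIXTURES.parent.mkdir(exist_ok=True)
    ensure_fixtures()
    manifest = json.loads((FIXTURES / "manifest.json").read_text())
    n_windows = len(manifest["files"]["windows"])
    print(f"fixture bundle under {FIXTURES} (master seed {MASTER_SEED}):")
    print(f"  planted Gaussian pair: gap {manifest['files']['ensemble_a.tsv']['gap']} sigma, "
          f"dim {manifest['files']['ensemble_a.tsv']['dim']}, "
          f"{manifest['files']['ensemble_a.tsv']['n_frames']} frames/side")
    print(f"  hinge dimer: anchor shift "
          f"{manifest['files']['hinge_dimer.pdb']['anchor_shift']} nm, "
          f"{manifest['files']['hinge_dimer.pdb']['n_frames']} frames")
    print(f"  umbrella windows: {n_windows} on a "
          f"{manifest['umbrella']['potential']['barrier_h']} kT double well")
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "fixture_manifest.json").write_text(json.dumps(manifest, indent=2))


if __name__ == "__main__":
    main()
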