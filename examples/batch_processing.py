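"""Batch fitting: one configured model applied to a directory of files.

Writes three synthetic measurements of the same sample (different noise,
same truth), fits all of them with the same starting model via the
stepwise workflow, and prints the per-file results table.
"""

import tempfile
from pathlib import Path

import sasmodelfit as sm
from sasmodelfit.cli import BatchJob, run_batch

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    for seed in (1, 2, 3):
        curve, truth = sm.generate(sm.gold_like_spec(seed=seed, n_points=300))
        sm.write_fixture(curve, tmp / f"sample_{seed}.pdh", dialect="pdh",
                         truth=truth)

    job = BatchJob(
        input_dir=str(tmp), pattern="*.pdh",
        config=sm.gold_like_config(N=1e-29, X0=4.0, s=0.5),
        workflow=("c0.N", "c0.X0", "c0.s"),
        output=str(tmp / "results.csv"),
    )
    records = run_batch(job)

    print(f"{'file':<14} {'X0 (nm)':>10} {'s (nm)':>10} {'chi2red':>8}")
    for r in records:
        if r["error"]:
            print(f"{r['file']:<14} FAILED: {r['error']}")
        else:
            print(f"{r['file']:<14} {r['params']['c0.X0']:>10.4f} "
                  f"{r['params']['c0.s']:>10.4f} {r['chi2red']:>8.3f}")

print()
print("All rows should scatter around the shared truth X0 = 4.48, s = 0.44;")
print("a corrupt file would appear as a FAILED row without stopping the rest.")
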