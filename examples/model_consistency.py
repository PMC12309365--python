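"""The central claim, rehearsed on synthetics: AIVE makes measurements
consistent across AI models.

Six simulated AI models segment the same two-shell phantom with systematic
boundary disagreement.  Three processing conditions are compared — raw
predictions, Gaussian-blurred predictions, and AIVE (blurred probability
multiplied into normalized electron intensity) — on two consistency metrics:
voxel-value disagreement (mean pairwise dV) and per-probe distance
reproducibility (range and relative absolute deviation across models).
"""

from voxtract.pipeline import consistency_benchmark

result = consistency_benchmark(k=6, seed=0)
print(f"{result.k_variants} simulated models, {result.n_probes} probes, "
      f"seed {result.seed}")
print()
print(f"{'condition':>10} {'mean dV (%)':>12} {'probe range (nm)':>17} "
      f"{'probe RAD':>10}")
for cond in ("raw", "blurred", "aive"):
    print(f"{cond:>10} {result.mean_dv[cond]:>12.2f} "
          f"{result.mean_range[cond]:>17.2f} {result.mean_rad[cond]:>10.3f}")
print()
print(f"raw > blurred > AIVE on dV and RAD: {result.ordering_holds()}")
print()
print("Blurring alone reduces voxel disagreement but AIVE, by letting the")
print("electron signal rather than each model's uncertain boundary place the")
print("surface, yields the most reproducible distance measurements.")
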