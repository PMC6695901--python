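"""Neutron reflectometry: two-contrast co-refinement of a mucin film.

Forward-models a Si/SiO2/mucin film (22 A thick, 60% mucin by volume) in
H2O and D2O, adds counting noise and instrument resolution, then
co-refines both contrasts with shared structural parameters.  Also
compares the film before and after a rinse that thins and hydrates it.
"""

from mucofilm import corefine
from mucofilm.pipeline import compare_states
from mucofilm.synthetic import NoiseSpec, make_nr_dataset

series = make_nr_dataset("bare_mucin", noise=NoiseSpec(level=1.0, seed=11))
fit = corefine(series, free=["mucin_thickness", "mucin_phi"], seed=11)
t, p = fit.params["mucin_thickness"], fit.params["mucin_phi"]
print("bare mucin film, two contrasts co-refined:")
print(f"  thickness = {t:.2f} A   (truth 22.0)")
print(f"  occupancy = {p:.3f}     (truth 0.60)")
print(f"  chi2 = {fit.chi2:.1f} over {fit.n_points} points; "
      f"per contrast: { {k: round(v, 1) for k, v in fit.per_dataset_chi2.items()} }")

# the same film after polymer exposure and rinsing: thinner, more hydrated
rinsed = make_nr_dataset("mucin_polymer", rinsed=True,
                         noise=NoiseSpec(level=1.0, seed=12))
fit2 = corefine(rinsed, free=["mucin_thickness", "mucin_phi"], seed=12)
print("\nafter polymer exposure and rinse (truth: 20 A, 50% occupancy):")
print(f"  thickness = {fit2.params['mucin_thickness']:.2f} A, "
      f"occupancy = {fit2.params['mucin_phi']:.3f}")

table = compare_states(fit, fit2)
d_t = table["mucin_thickness"]
d_p = table["mucin_phi"]
print("\nchange table (after - before):")
print(f"  thickness: {d_t['delta']:+.2f} A")
print(f"  occupancy: {d_p['delta']:+.3f}")
print("The rinse removes entangled material: the layer thins by ~2 A and")
print("its solvent content rises by ~10 percentage points.")
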