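"""Natural-spline spectral regression with a known injected effect.

Generates a 300-species synthetic community in which each unit (percent)
of blue reflectance lowers the log10 VOC index by 0.04 and each log10
unit of surface-area:weight raises it by 0.5, then fits the spline
spectral regression and back-calculates per-band cumulative effects with
delta-method standard errors.  The blue effect comes back negative and
highly significant but attenuated (the 5-df spline smooths the sharp
band boundary); the size coefficient is unbiased.
"""

from fruitsignals import (
    CommunityConfig,
    band_effects,
    build_basis,
    fit_model,
    generate_community,
)

config = CommunityConfig(n_species=300, blue_voc_effect=-0.04,
                         saw_voc_effect=0.5, seed=7)
community = generate_community(config)
basis = build_basis()  # knots 350-590 nm, referent 650 nm, five columns

fit = fit_model(community.records, community.spectra, basis)
print(
    f"n = {fit.n_obs}, R^2 = {fit.r_squared:.3f}, "
    f"spectral F({fit.f_df[0]}, {fit.f_df[1]}) = {fit.f_stat:.2f}, "
    f"p = {fit.f_p:.2g}"
)
print(f"log10(SA:W) coefficient: {fit.coefficients['log_saw']:+.3f} "
      f"(injected +0.500)\n")
print("band   effect      SE        p        (log10 VOC per % reflectance)")
for band, eff in band_effects(fit, basis).items():
    print(
        f"{band:<6} {eff.cumulative_coefficient:+.4f}   {eff.std_error:.4f}"
        f"   {eff.p_two_tailed:.2g}"
    )
print(
    "\nThe blue band carries the injected negative effect; the other bands"
    "\nare indistinguishable from zero."
)
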