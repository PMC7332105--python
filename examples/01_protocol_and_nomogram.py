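"""The spectral stimulus schedule and the opsin nomogram weights.

The recording protocol delivers 280 monochromatic flashes: ten wavelength
blocks (650 nm twice, as a stability index), seven irradiance steps 0.5 log
units apart, four replicates per step.  The nomogram weight A(λmax, λ)
converts a pigment's peak semi-saturation into its effective value at any
stimulus wavelength.
"""
import conespect as cs

protocol = cs.default_protocol()
print(f"flashes: {len(protocol.stimuli)}, combinations: {protocol.combo_count}")
print(f"block order: {protocol.blocks}")
print(f"brightest 650 nm stimulus: 10^{protocol.log_irradiance(650, 7):.1f} quanta/um^2/s")
print(f"dimmest   650 nm stimulus: 10^{protocol.log_irradiance(650, 1):.1f} (3 log units lower)")

print("\nspectral weight A(553.7, lambda) for the larval red cone:")
for lam in (553.7, 490.0, 610.0, 650.0):
    a = cs.nomogram_A("r", 553.7, lam)
    print(f"  {lam:5.1f} nm: A = {a:8.2f}  (effective semi-saturation x{a:.1f})")
# A is 1 at the pigment peak and grows off-peak: the same cone needs ~20x
# more light at 650 nm than at its 553.7 nm peak to reach half-saturation.
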