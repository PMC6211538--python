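# fractsans molecular-weight constants v1
# key	value	unit	source
rho_protein	1.37	g/cm^3	average protein mass density
porod_volume_per_dalton	1.60	A^3/Da	Porod-volume-to-mass rule (ATSAS convention, Petoukhov et al. 2012)
fischer_qmax_rg	8.0	dimensionless	truncation q_max = value / R_g for size-aware invariant
water_volume	30.0	A^3	molecular volume of water
waters_per_bead	4.13	dimensionless	water molecules represented by one hydration bead
shell_density_excess	0.10	dimensionless	hydration-layer density excess over bulk water
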