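# Default element-wise tight-binding parameterization (GFN2-style).
#
# Units: shell levels in eV; hardness (gam), third-order (gam3), spin
# constants (W) and Hubbard U in Hartree; radii in Angstrom; Slater
# exponents dimensionless; repulsion alpha in Bohr^-3/2.
#
# Shells are listed in increasing angular momentum (s, p, d); `pqn` gives the
# principal quantum number of each shell.  `W` is the symmetric shell-pair
# spin-polarization constant matrix; `U` the per-shell Hubbard parameter
# (zero unless a +U calculation switches it on).

[global]
alpha_u = 0.5
rep_kexp = 1.5
rep_kexp_light = 1.0
k_shell = { s = 1.85, p = 2.23, d = 2.23 }
k_en = 0.02
wexp = 0.5
gexp = 2.0
third_order_shell_scale = [1.0, 0.5, 0.25]
cn_radius_scale = 1.3333333333333333
mp_dmp3 = 3.0
mp_dmp5 = 4.0
mp_kexp = 4.0
mp_shift = 1.2
mp_rmax = 5.0

[element.H]
shells = ["s"]
pqn = [1]
levels_ev = [-10.707211]
slater_exp = [1.230]
ref_occ = [1.0]
k_cn_ev = [-0.10]
shell_poly = [0.0]
gam = 0.405771
shell_hardness = [1.0]
gam3 = 0.08
rep_alpha = 2.213717
rep_zeff = 1.105388
en = 2.20
cov_radius = 0.32
dip_kernel = -0.006
quad_kernel = -0.002
mp_rad = 1.6
mp_vcn = 1.0
W = [[-0.034]]
U = [0.0]

[element.Li]
shells = ["s", "p"]
pqn = [2, 2]
levels_ev = [-4.900, -2.218]
slater_exp = [0.80, 0.70]
ref_occ = [1.0, 0.0]
k_cn_ev = [-0.05, -0.03]
shell_poly = [0.0, 0.0]
gam = 0.175
shell_hardness = [1.0, 1.0]
gam3 = 0.04
rep_alpha = 0.55
rep_zeff = 2.0
en = 0.98
cov_radius = 1.33
dip_kernel = -0.002
quad_kernel = -0.001
mp_rad = 3.0
mp_vcn = 1.0
W = [[-0.012, -0.010], [-0.010, -0.011]]
U = [0.0, 0.0]

[element.C]
shells = ["s", "p"]
pqn = [2, 2]
levels_ev = [-13.971, -10.063]
slater_exp = [2.096, 1.776]
ref_occ = [2.0, 2.0]
k_cn_ev = [-0.30, 0.10]
shell_poly = [0.0, 0.0]
gam = 0.50
shell_hardness = [1.0, 1.0]
gam3 = 0.10
rep_alpha = 1.20
rep_zeff = 4.3
en = 2.55
cov_radius = 0.75
dip_kernel = -0.007
quad_kernel = -0.002
mp_rad = 2.6
mp_vcn = 4.0
W = [[-0.023, -0.021], [-0.021, -0.022]]
U = [0.0, 0.0]

[element.N]
shells = ["s", "p"]
pqn = [2, 2]
levels_ev = [-16.686, -12.524]
slater_exp = [2.339, 2.048]
ref_occ = [2.0, 3.0]
k_cn_ev = [-0.35, 0.12]
shell_poly = [0.0, 0.0]
gam = 0.56
shell_hardness = [1.0, 1.0]
gam3 = 0.12
rep_alpha = 1.40
rep_zeff = 5.3
en = 3.04
cov_radius = 0.71
dip_kernel = -0.008
quad_kernel = -0.002
mp_rad = 2.5
mp_vcn = 3.0
W = [[-0.026, -0.025], [-0.025, -0.026]]
U = [0.0, 0.0]

[element.O]
shells = ["s", "p"]
pqn = [2, 2]
levels_ev = [-20.230, -14.100]
slater_exp = [2.440, 2.243]
ref_occ = [2.0, 4.0]
k_cn_ev = [-0.35, 0.12]
shell_poly = [0.0, 0.0]
gam = 0.59
shell_hardness = [1.0, 1.0]
gam3 = 0.14
rep_alpha = 1.60
rep_zeff = 6.1
en = 3.44
cov_radius = 0.63
dip_kernel = -0.009
quad_kernel = -0.002
mp_rad = 2.4
mp_vcn = 2.0
W = [[-0.028, -0.027], [-0.027, -0.028]]
U = [0.0, 0.0]

[element.F]
shells = ["s", "p"]
pqn = [2, 2]
levels_ev = [-23.458, -15.747]
slater_exp = [2.417, 2.308]
ref_occ = [2.0, 5.0]
k_cn_ev = [-0.40, 0.10]
shell_poly = [0.0, 0.0]
gam = 0.532
shell_hardness = [1.0, 1.0]
gam3 = 0.15
rep_alpha = 2.00
rep_zeff = 6.9
en = 3.98
cov_radius = 0.64
dip_kernel = -0.010
quad_kernel = -0.002
mp_rad = 2.3
mp_vcn = 1.0
W = [[-0.030, -0.028], [-0.028, -0.030]]
U = [0.0, 0.0]

[element.Fe]
shells = ["s", "p", "d"]
pqn = [4, 4, 3]
levels_ev = [-6.30, -2.70, -6.80]
slater_exp = [1.55, 1.20, 2.30]
ref_occ = [2.0, 0.0, 6.0]
k_cn_ev = [-0.10, 0.05, -0.20]
shell_poly = [0.0, 0.0, 0.0]
gam = 0.35
shell_hardness = [1.0, 1.0, 1.0]
gam3 = 0.05
rep_alpha = 1.00
rep_zeff = 7.5
en = 1.83
cov_radius = 1.16
dip_kernel = -0.005
quad_kernel = -0.002
mp_rad = 3.5
mp_vcn = 6.0
W = [[-0.016, -0.012, -0.003], [-0.012, -0.029, -0.001], [-0.003, -0.001, -0.026]]
U = [0.0, 0.0, 0.0]
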