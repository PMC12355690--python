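# Dreiding-style nonbonded parameters.
#
# Lennard-Jones 12-6:  E = D0 * [ (R0/r)^12 - 2*(R0/r)^6 ]   (kcal/mol, Å)
# values from the published generic Dreiding parameter set; all carbons share
# one vdW type, as do all nitrogens and oxygens.  The hydrogen-bonding
# hydrogen H__HB is given a near-zero well depth because the explicit 12-10
# hydrogen-bond term takes over for donor-H...acceptor contacts.
#
# Hydrogen bond 12-10:  E = D_hb * [ 5*(R_hb/r_DA)^12 - 6*(R_hb/r_DA)^10 ] * cos^4(theta)
# active for donor-acceptor distance r_DA < r_cut and D-H...A angle > theta_min.
# D_hb = 4.0 kcal/mol is the charge-aware Dreiding choice (9.5 is the
# no-charges variant); R_hb = 2.75 Å.

[lj]
H_ = { r0 = 3.195, d0 = 0.0152 }
H__HB = { r0 = 3.195, d0 = 0.0001 }
C_3 = { r0 = 3.8983, d0 = 0.0951 }
C_2 = { r0 = 3.8983, d0 = 0.0951 }
C_1 = { r0 = 3.8983, d0 = 0.0951 }
C_R = { r0 = 3.8983, d0 = 0.0951 }
N_3 = { r0 = 3.6621, d0 = 0.0774 }
N_2 = { r0 = 3.6621, d0 = 0.0774 }
N_1 = { r0 = 3.6621, d0 = 0.0774 }
N_R = { r0 = 3.6621, d0 = 0.0774 }
O_3 = { r0 = 3.4046, d0 = 0.0957 }
O_2 = { r0 = 3.4046, d0 = 0.0957 }
O_R = { r0 = 3.4046, d0 = 0.0957 }
S_3 = { r0 = 4.03, d0 = 0.344 }
F_3 = { r0 = 3.472, d0 = 0.0725 }
Cl_3 = { r0 = 3.9503, d0 = 0.2833 }
Br_3 = { r0 = 3.95, d0 = 0.37 }
P_3 = { r0 = 4.15, d0 = 0.32 }

[hbond]
d_hb = 4.0
r_hb = 2.75
r_cut = 4.5
theta_min_deg = 90.0

[electrostatics]
# distance-dependent dielectric eps(r) = eps0 * r
eps0 = 1.0

[combining]
# geometric mixing is the canonical Dreiding prescription for both R0 and D0
r0 = "geometric"
d0 = "geometric"
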