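# Calibrated wild-type ("WTsim") parameter profile for the neuronal
# respiratory-chain model.  Units: concentrations M, time s, dpsi mV,
# free energies kJ/mol.  Activity constants are calibrated so that the
# unperturbed steady state lies inside literature ranges (matrix pH,
# membrane potential, cytosolic ATP) and drug responses match live-cell
# calibration measurements; thermodynamic constants and binding constants
# are literature values of the Beard oxphos model family.
#
# Assumptions flagged (under-determined in the sources):
#   - free matrix Mg2+ held constant (Mg_x state, dMg/dt = 0)
#   - matrix H+ buffering via the effective x_buff*H_x capacity form
#   - adenylate kinase inactive by default (X_AK = 0, fixed AMP_c)
parameters:
  X_DH: 2.0e-3
  X_C1: 4.0
  X_C3: 0.6
  X_C4: 3.0e-4
  X_F1: 1.0
  X_ANT: 0.03
  X_Hle: 19.0
  X_PiH: 3.3914e5
  X_KH: 2.9802e7
  X_AK: 0.0
  X_ATPase_c: 1.2e-4
  NADtot: 2.97e-3
  Qtot: 1.35e-3
  Ctot: 2.7e-3
  r_DH: 4.559
  dpsi_ref_DH: 40.0
  delta_psi_DH: 30.0
  k_Pi1: 1.553e-4
  k_Pi2: 8.222e-4
  k_sat_C1: 4.4e-5
  k_sat_C3: 0.9e-5
  k_sat_C4: 2.5
  K_AtC: 1.5e-4
  k_Pi3: 1.928e-4
  k_Pi4: 2.531e-2
  k_O2: 1.2e-6
  k_mADP: 3.5e-6
  theta_ANT: 0.60
  k_PiH: 4.5082e-4
  Keq_AK: 0.4331
  T: 310.15
  dG_C1o: -69.37
  dG_C3o: -32.53
  dG_C4o: -122.94
  dG_F1o: 36.03
  n_A: 3.0
  K_DT: 24.0e-6
  K_DD: 347.0e-6
  pKa_ATP: 6.48
  pKa_ADP: 6.38
  pKa_Pi: 6.75
  CIM: 6.7568e-6
  W_x: 0.6
  W_i: 0.066
  W_c: 15.0
  x_buff: 100.0
  x_AM: 100.0
  x_PM: 300.0
  O2: 2.6e-5
  pH_c: 7.2
  K_c: 0.14
  Mg_c: 4.0e-4
  AMP_c: 1.0e-5
initial_state:
  dpsi: 160.0
  NADH_x: 1.5e-3
  QH2: 0.8e-3
  Cred: 1.0e-3
  ATP_x: 3.0e-3
  ADP_x: 7.0e-3
  Pi_x: 6.0e-4
  ATP_i: 2.0e-3
  ADP_i: 0.5e-3
  Pi_i: 3.0e-4
  ATP_c: 2.4e-3
  ADP_c: 1.0e-4
  Pi_c: 3.0e-4
  H_x: 3.16e-8
  K_x: 0.079
  Mg_x: 4.0e-4
# literature ranges used by the calibration checks (reporting units)
literature_ranges:
  pH_x: [7.2, 7.8]
  dpsi_mV: [108.0, 167.0]
  ATP_c_mM: [0.5, 5.0]
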