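name: arm4d19
gravity:
- 0.0
- 0.0
- -9.81
joints:
- name: gh_plane
  parent: ground
  origin:
  - 0.0
  - 0.0
  - 0.0
  axis:
  - 0.0
  - 0.0
  - 1.0
  limits:
  - -1.5707963267948966
  - 1.5707963267948966
- name: gh_elev
  parent: gh_plane
  origin:
  - 0.0
  - 0.0
  - 0.0
  axis:
  - 1.0
  - 0.0
  - 0.0
  limits:
  - -2.0
  - 1.5707963267948966
- name: gh_rot
  parent: gh_elev
  origin:
  - 0.0
  - 0.0
  - 0.0
  axis:
  - 0.0
  - 0.0
  - 1.0
  limits:
  - -1.5707963267948966
  - 1.5707963267948966
- name: elbow_flex
  parent: gh_rot
  origin:
  - 0.0
  - 0.0
  - -0.3
  axis:
  - 0.0
  - -1.0
  - 0.0
  limits:
  - -0.5
  - 2.1
segments:
- name: thorax
  frame: ground
  mass: 0.0
  com:
  - 0.0
  - 0.0
  - 0.0
  inertia:
  - 0.0
  - 0.0
  - 0.0
- name: humerus
  frame: gh_rot
  mass: 2.05
  com:
  - 0.0
  - 0.0
  - -0.13
  inertia:
  - 0.014
  - 0.014
  - 0.0025
- name: ulna
  frame: elbow_flex
  mass: 1.25
  com:
  - 0.0
  - 0.0
  - -0.11
  inertia:
  - 0.0075
  - 0.0075
  - 0.0011
- name: radius
  frame: elbow_flex
  mass: 0.35
  com:
  - 0.01
  - 0.0
  - -0.15
  inertia:
  - 0.003
  - 0.003
  - 0.0004
markers:
- name: m_delt
  segment: humerus
  position:
  - 0.0
  - 0.035
  - -0.12
- name: m_shaft
  segment: humerus
  position:
  - 0.005
  - 0.03
  - -0.2
- name: m_cond_med
  segment: humerus
  position:
  - 0.0
  - -0.035
  - -0.285
- name: m_cond_lat
  segment: humerus
  position:
  - 0.0
  - 0.035
  - -0.285
- name: m_olecranon
  segment: ulna
  position:
  - -0.035
  - 0.0
  - 0.01
- name: m_ulna_lat
  segment: ulna
  position:
  - 0.0
  - 0.028
  - -0.15
- name: m_uln_styloid
  segment: ulna
  position:
  - 0.0
  - -0.02
  - -0.235
- name: m_rad_styloid
  segment: radius
  position:
  - 0.02
  - 0.02
  - -0.235
muscles:
- name: pec_clav
  f_iso_max: 364.4
  l_opt: 0.05
  l_ts: 0.06047033986480514
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - 0.05
    - -0.1
    - 0.01
  - segment: humerus
    position:
    - 0.015
    - 0.005
    - -0.06
- name: pec_ster
  f_iso_max: 515.4
  l_opt: 0.05678905038861087
  l_ts: 0.055472790717713535
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - 0.06
    - -0.12
    - -0.03
  - segment: humerus
    position:
    - 0.015
    - 0.005
    - -0.07
- name: pec_rib
  f_iso_max: 390.5
  l_opt: 0.05
  l_ts: 0.05365595413557549
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - 0.05
    - -0.12
    - -0.09
  - segment: humerus
    position:
    - 0.012
    - 0.005
    - -0.075
- name: lat_thor
  f_iso_max: 389.1
  l_opt: 0.05
  l_ts: 0.05356802334239087
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - -0.07
    - -0.1
    - -0.08
  - segment: humerus
    position:
    - 0.008
    - -0.005
    - -0.09
- name: lat_lumb
  f_iso_max: 287.3
  l_opt: 0.05
  l_ts: 0.0707317084168863
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - -0.07
    - -0.11
    - -0.14
  - segment: humerus
    position:
    - 0.008
    - -0.005
    - -0.1
- name: lat_ilio
  f_iso_max: 204.7
  l_opt: 0.05
  l_ts: 0.09514884766519956
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - -0.06
    - -0.11
    - -0.2
  - segment: humerus
    position:
    - 0.008
    - -0.005
    - -0.11
- name: delt_ant
  f_iso_max: 1142.6
  l_opt: 0.05
  l_ts: 0.07474650898518555
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - 0.035
    - -0.03
    - 0.015
  - segment: humerus
    position:
    - 0.012
    - 0.022
    - -0.11
- name: delt_mid
  f_iso_max: 1142.6
  l_opt: 0.05
  l_ts: 0.13833787624604454
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - 0.0
    - 0.005
    - 0.035
  - segment: thorax
    position:
    - 0.0
    - 0.045
    - 0.015
  - segment: humerus
    position:
    - 0.002
    - 0.028
    - -0.11
- name: delt_post
  f_iso_max: 259.9
  l_opt: 0.05
  l_ts: 0.07484500075416857
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - -0.04
    - -0.03
    - 0.015
  - segment: humerus
    position:
    - -0.012
    - 0.022
    - -0.11
- name: supra
  f_iso_max: 487.8
  l_opt: 0.05
  l_ts: 0.07438917909661047
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - -0.045
    - -0.045
    - 0.01
  - segment: thorax
    position:
    - -0.005
    - 0.0
    - 0.035
  - segment: humerus
    position:
    - 0.0
    - 0.022
    - -0.015
- name: infra
  f_iso_max: 1210.8
  l_opt: 0.05
  l_ts: 0.011828787690016593
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - -0.065
    - -0.04
    - -0.01
  - segment: humerus
    position:
    - -0.018
    - 0.016
    - -0.02
- name: subsc
  f_iso_max: 1377.8
  l_opt: 0.05
  l_ts: 0.0362804338357776
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - -0.05
    - -0.05
    - -0.015
  - segment: humerus
    position:
    - 0.018
    - 0.012
    - -0.02
- name: tri_long
  f_iso_max: 798.5
  l_opt: 0.05
  l_ts: 0.2517659570249109
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - -0.045
    - -0.02
    - -0.005
  - segment: humerus
    position:
    - -0.02
    - 0.0
    - -0.28
  - segment: ulna
    position:
    - -0.025
    - 0.0
    - 0.012
- name: tri_lat
  f_iso_max: 624.3
  l_opt: 0.05
  l_ts: 0.16132774479701878
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: humerus
    position:
    - -0.01
    - 0.008
    - -0.1
  - segment: humerus
    position:
    - -0.02
    - 0.0
    - -0.28
  - segment: ulna
    position:
    - -0.025
    - 0.0
    - 0.012
- name: tri_med
  f_iso_max: 624.3
  l_opt: 0.05
  l_ts: 0.12145725842802606
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: humerus
    position:
    - -0.01
    - -0.008
    - -0.14
  - segment: humerus
    position:
    - -0.02
    - 0.0
    - -0.28
  - segment: ulna
    position:
    - -0.025
    - 0.0
    - 0.012
- name: brachiorad
  f_iso_max: 261.3
  l_opt: 0.06802900153053704
  l_ts: 0.15414134227686732
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: humerus
    position:
    - 0.008
    - 0.02
    - -0.23
  - segment: radius
    position:
    - 0.015
    - 0.01
    - -0.18
- name: brachialis
  f_iso_max: 987.3
  l_opt: 0.05
  l_ts: 0.09735404279348374
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: humerus
    position:
    - 0.012
    - 0.0
    - -0.16
  - segment: ulna
    position:
    - 0.018
    - 0.0
    - -0.03
- name: bic_long
  f_iso_max: 624.3
  l_opt: 0.05
  l_ts: 0.2947735384045639
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - 0.012
    - 0.01
    - 0.02
  - segment: humerus
    position:
    - 0.022
    - 0.005
    - -0.05
  - segment: humerus
    position:
    - 0.022
    - 0.0
    - -0.27
  - segment: radius
    position:
    - 0.015
    - 0.0
    - -0.045
- name: bic_short
  f_iso_max: 435.6
  l_opt: 0.06487039249728455
  l_ts: 0.2538711852549824
  v_max: 10.0
  tau_act: 0.015
  tau_deact: 0.06
  delay: 0.02
  path:
  - segment: thorax
    position:
    - 0.035
    - -0.015
    - 0.005
  - segment: humerus
    position:
    - 0.02
    - -0.005
    - -0.27
  - segment: radius
    position:
    - 0.015
    - 0.0
    - -0.045
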