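# 13-link whole-body model: segment endpoints (marker centroids), Dempster
# mass fractions and segment-CoM position ratios as tabulated in Winter's
# "Biomechanics and Motor Control of Human Movement".  The trunk fraction is
# the thorax+abdomen share and the pelvis fraction the pelvic share of
# Winter's combined trunk value, so that the 13 fractions sum to 1.
# com_ratio is the fractional distance of the segment CoM from the proximal
# endpoint along the proximal->distal line.
version: 1
source: "Dempster anthropometrics via Winter's tabulation"
segments:
  - name: head_neck
    proximal_markers: [C7]
    distal_markers: [HEAD_TOP]
    mass_fraction: 0.081
    com_ratio: 0.5
  - name: trunk
    proximal_markers: [L_SHOULDER, R_SHOULDER]
    distal_markers: [L_ASIS, R_ASIS]
    mass_fraction: 0.355
    com_ratio: 0.5
  - name: pelvis
    proximal_markers: [L_ASIS, R_ASIS]
    distal_markers: [SACRUM]
    mass_fraction: 0.142
    com_ratio: 0.5
  - name: upper_arm_l
    proximal_markers: [L_SHOULDER]
    distal_markers: [L_ELBOW]
    mass_fraction: 0.028
    com_ratio: 0.436
  - name: upper_arm_r
    proximal_markers: [R_SHOULDER]
    distal_markers: [R_ELBOW]
    mass_fraction: 0.028
    com_ratio: 0.436
  - name: forearm_hand_l
    proximal_markers: [L_ELBOW]
    distal_markers: [L_WRIST]
    mass_fraction: 0.022
    com_ratio: 0.682
  - name: forearm_hand_r
    proximal_markers: [R_ELBOW]
    distal_markers: [R_WRIST]
    mass_fraction: 0.022
    com_ratio: 0.682
  - name: thigh_l
    proximal_markers: [L_HIP]
    distal_markers: [L_KNEE]
    mass_fraction: 0.100
    com_ratio: 0.433
  - name: thigh_r
    proximal_markers: [R_HIP]
    distal_markers: [R_KNEE]
    mass_fraction: 0.100
    com_ratio: 0.433
  - name: shank_l
    proximal_markers: [L_KNEE]
    distal_markers: [L_ANKLE]
    mass_fraction: 0.0465
    com_ratio: 0.433
  - name: shank_r
    proximal_markers: [R_KNEE]
    distal_markers: [R_ANKLE]
    mass_fraction: 0.0465
    com_ratio: 0.433
  - name: foot_l
    proximal_markers: [L_HEEL]
    distal_markers: [L_TOE]
    mass_fraction: 0.0145
    com_ratio: 0.5
  - name: foot_r
    proximal_markers: [R_HEEL]
    distal_markers: [R_TOE]
    mass_fraction: 0.0145
    com_ratio: 0.5
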