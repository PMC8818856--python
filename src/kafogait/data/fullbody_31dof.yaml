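# Declarative full-body topology of the torque-driven subject + device model.
# 31 unlocked degrees of freedom: 6 pelvis-ground, 3 per hip, 1 per knee,
# 3 lumbosacral, 3 per shoulder, 2 per elbow, 2 per wrist.  Ankle, subtalar
# and metatarsophalangeal joints are locked at 0 deg by the orthosis; crutches
# are welded to the hands and orthosis links welded to thigh/shank, so none of
# them contribute coordinates.  This schema is declarative only: planar
# dynamics run on the 12-DOF sagittal reduction (see PlanarModel).
name: fullbody_crutch_kafo
joints:
  - name: ground_pelvis
    parent: ground
    child: pelvis
    dofs: [pelvis_tilt, pelvis_list, pelvis_rotation, pelvis_tx, pelvis_ty, pelvis_tz]
  - name: hip_r
    parent: pelvis
    child: femur_r
    dofs: [hip_flexion_r, hip_adduction_r, hip_rotation_r]
  - name: knee_r
    parent: femur_r
    child: tibia_r
    dofs: [knee_angle_r]
  - name: ankle_r
    parent: tibia_r
    child: talus_r
    dofs: [ankle_angle_r]
    locked: [ankle_angle_r]
  - name: subtalar_r
    parent: talus_r
    child: calcn_r
    dofs: [subtalar_angle_r]
    locked: [subtalar_angle_r]
  - name: mtp_r
    parent: calcn_r
    child: toes_r
    dofs: [mtp_angle_r]
    locked: [mtp_angle_r]
  - name: hip_l
    parent: pelvis
    child: femur_l
    dofs: [hip_flexion_l, hip_adduction_l, hip_rotation_l]
  - name: knee_l
    parent: femur_l
    child: tibia_l
    dofs: [knee_angle_l]
  - name: ankle_l
    parent: tibia_l
    child: talus_l
    dofs: [ankle_angle_l]
    locked: [ankle_angle_l]
  - name: subtalar_l
    parent: talus_l
    child: calcn_l
    dofs: [subtalar_angle_l]
    locked: [subtalar_angle_l]
  - name: mtp_l
    parent: calcn_l
    child: toes_l
    dofs: [mtp_angle_l]
    locked: [mtp_angle_l]
  - name: back
    parent: pelvis
    child: torso
    dofs: [lumbar_extension, lumbar_bending, lumbar_rotation]
  - name: shoulder_r
    parent: torso
    child: humerus_r
    dofs: [arm_flex_r, arm_add_r, arm_rot_r]
  - name: elbow_r
    parent: humerus_r
    child: ulna_r
    dofs: [elbow_flex_r, pro_sup_r]
  - name: wrist_r
    parent: ulna_r
    child: hand_r
    dofs: [wrist_flex_r, wrist_dev_r]
  - name: shoulder_l
    parent: torso
    child: humerus_l
    dofs: [arm_flex_l, arm_add_l, arm_rot_l]
  - name: elbow_l
    parent: humerus_l
    child: ulna_l
    dofs: [elbow_flex_l, pro_sup_l]
  - name: wrist_l
    parent: ulna_l
    child: hand_l
    dofs: [wrist_flex_l, wrist_dev_l]
welds:
  - {name: crutch_r, host: hand_r}
  - {name: crutch_l, host: hand_l}
  - {name: orthosis_thigh_r, host: femur_r}
  - {name: orthosis_thigh_l, host: femur_l}
  - {name: orthosis_shank_r, host: tibia_r}
  - {name: orthosis_shank_l, host: tibia_l}
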