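# Default VOI -> composite-region map for focal amyloid staging.
#
# AAL-style lateralized volumes of interest grouped into 5 lobes x 2 hemispheres
# = 10 composite regions (frontal, lateral temporal, parietal, cingulate and
# striatum, left/right). Edit or replace this file to use a different atlas or
# VOI selection; names only need to match the VOI table / label table in use.
vois:
- {voi: Frontal_Sup_L, lobe: frontal, hemisphere: left}
- {voi: Frontal_Sup_R, lobe: frontal, hemisphere: right}
- {voi: Frontal_Mid_L, lobe: frontal, hemisphere: left}
- {voi: Frontal_Mid_R, lobe: frontal, hemisphere: right}
- {voi: Frontal_Sup_Medial_L, lobe: frontal, hemisphere: left}
- {voi: Frontal_Sup_Medial_R, lobe: frontal, hemisphere: right}
- {voi: Frontal_Inf_Oper_L, lobe: frontal, hemisphere: left}
- {voi: Frontal_Inf_Oper_R, lobe: frontal, hemisphere: right}
- {voi: Frontal_Inf_Tri_L, lobe: frontal, hemisphere: left}
- {voi: Frontal_Inf_Tri_R, lobe: frontal, hemisphere: right}
- {voi: Supp_Motor_Area_L, lobe: frontal, hemisphere: left}
- {voi: Supp_Motor_Area_R, lobe: frontal, hemisphere: right}
- {voi: Frontal_Sup_Orb_L, lobe: frontal, hemisphere: left}
- {voi: Frontal_Sup_Orb_R, lobe: frontal, hemisphere: right}
- {voi: Frontal_Mid_Orb_L, lobe: frontal, hemisphere: left}
- {voi: Frontal_Mid_Orb_R, lobe: frontal, hemisphere: right}
- {voi: Frontal_Inf_Orb_L, lobe: frontal, hemisphere: left}
- {voi: Frontal_Inf_Orb_R, lobe: frontal, hemisphere: right}
- {voi: Temporal_Sup_L, lobe: lateral_temporal, hemisphere: left}
- {voi: Temporal_Sup_R, lobe: lateral_temporal, hemisphere: right}
- {voi: Temporal_Mid_L, lobe: lateral_temporal, hemisphere: left}
- {voi: Temporal_Mid_R, lobe: lateral_temporal, hemisphere: right}
- {voi: Temporal_Inf_L, lobe: lateral_temporal, hemisphere: left}
- {voi: Temporal_Inf_R, lobe: lateral_temporal, hemisphere: right}
- {voi: Parietal_Sup_L, lobe: parietal, hemisphere: left}
- {voi: Parietal_Sup_R, lobe: parietal, hemisphere: right}
- {voi: Parietal_Inf_L, lobe: parietal, hemisphere: left}
- {voi: Parietal_Inf_R, lobe: parietal, hemisphere: right}
- {voi: SupraMarginal_L, lobe: parietal, hemisphere: left}
- {voi: SupraMarginal_R, lobe: parietal, hemisphere: right}
- {voi: Angular_L, lobe: parietal, hemisphere: left}
- {voi: Angular_R, lobe: parietal, hemisphere: right}
- {voi: Precuneus_L, lobe: parietal, hemisphere: left}
- {voi: Precuneus_R, lobe: parietal, hemisphere: right}
- {voi: Cingulum_Ant_L, lobe: cingulate, hemisphere: left}
- {voi: Cingulum_Ant_R, lobe: cingulate, hemisphere: right}
- {voi: Cingulum_Post_L, lobe: cingulate, hemisphere: left}
- {voi: Cingulum_Post_R, lobe: cingulate, hemisphere: right}
- {voi: Caudate_L, lobe: striatum, hemisphere: left}
- {voi: Caudate_R, lobe: striatum, hemisphere: right}
- {voi: Putamen_L, lobe: striatum, hemisphere: left}
- {voi: Putamen_R, lobe: striatum, hemisphere: right}
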