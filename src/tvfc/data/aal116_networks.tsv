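roi_label	network
Precentral_L	sensorimotor
Precentral_R	sensorimotor
Frontal_Sup_L	frontoparietal
Frontal_Sup_R	frontoparietal
Frontal_Sup_Orb_L	frontoparietal
Frontal_Sup_Orb_R	frontoparietal
Frontal_Mid_L	frontoparietal
Frontal_Mid_R	frontoparietal
Frontal_Mid_Orb_L	frontoparietal
Frontal_Mid_Orb_R	frontoparietal
Frontal_Inf_Oper_L	cingulo_opercular
Frontal_Inf_Oper_R	cingulo_opercular
Frontal_Inf_Tri_L	frontoparietal
Frontal_Inf_Tri_R	frontoparietal
Frontal_Inf_Orb_L	cingulo_opercular
Frontal_Inf_Orb_R	cingulo_opercular
Rolandic_Oper_L	cingulo_opercular
Rolandic_Oper_R	cingulo_opercular
Supp_Motor_Area_L	sensorimotor
Supp_Motor_Area_R	sensorimotor
Olfactory_L	subcortical
Olfactory_R	subcortical
Frontal_Sup_Medial_L	default_mode
Frontal_Sup_Medial_R	default_mode
Frontal_Med_Orb_L	default_mode
Frontal_Med_Orb_R	default_mode
Rectus_L	default_mode
Rectus_R	default_mode
Insula_L	salience
Insula_R	salience
Cingulum_Ant_L	salience
Cingulum_Ant_R	salience
Cingulum_Mid_L	cingulo_opercular
Cingulum_Mid_R	cingulo_opercular
Cingulum_Post_L	default_mode
Cingulum_Post_R	default_mode
Hippocampus_L	subcortical
Hippocampus_R	subcortical
ParaHippocampal_L	subcortical
ParaHippocampal_R	subcortical
Amygdala_L	subcortical
Amygdala_R	subcortical
Calcarine_L	visual
Calcarine_R	visual
Cuneus_L	visual
Cuneus_R	visual
Lingual_L	visual
Lingual_R	visual
Occipital_Sup_L	visual
Occipital_Sup_R	visual
Occipital_Mid_L	visual
Occipital_Mid_R	visual
Occipital_Inf_L	visual
Occipital_Inf_R	visual
Fusiform_L	visual
Fusiform_R	visual
Postcentral_L	sensorimotor
Postcentral_R	sensorimotor
Parietal_Sup_L	frontoparietal
Parietal_Sup_R	frontoparietal
Parietal_Inf_L	attention
Parietal_Inf_R	attention
SupraMarginal_L	attention
SupraMarginal_R	attention
Angular_L	default_mode
Angular_R	default_mode
Precuneus_L	default_mode
Precuneus_R	default_mode
Paracentral_Lobule_L	sensorimotor
Paracentral_Lobule_R	sensorimotor
Caudate_L	subcortical
Caudate_R	subcortical
Putamen_L	subcortical
Putamen_R	subcortical
Pallidum_L	subcortical
Pallidum_R	subcortical
Thalamus_L	thalamus
Thalamus_R	thalamus
Heschl_L	auditory
Heschl_R	auditory
Temporal_Sup_L	auditory
Temporal_Sup_R	auditory
Temporal_Pole_Sup_L	attention
Temporal_Pole_Sup_R	attention
Temporal_Mid_L	default_mode
Temporal_Mid_R	default_mode
Temporal_Pole_Mid_L	default_mode
Temporal_Pole_Mid_R	default_mode
Temporal_Inf_L	attention
Temporal_Inf_R	attention
Cerebelum_Crus1_L	cerebellum
Cerebelum_Crus1_R	cerebellum
Cerebelum_Crus2_L	cerebellum
Cerebelum_Crus2_R	cerebellum
Cerebelum_3_L	cerebellum
Cerebelum_3_R	cerebellum
Cerebelum_4_5_L	cerebellum
Cerebelum_4_5_R	cerebellum
Cerebelum_6_L	cerebellum
Cerebelum_6_R	cerebellum
Cerebelum_7b_L	cerebellum
Cerebelum_7b_R	cerebellum
Cerebelum_8_L	cerebellum
Cerebelum_8_R	cerebellum
Cerebelum_9_L	cerebellum
Cerebelum_9_R	cerebellum
Cerebelum_10_L	cerebellum
Cerebelum_10_R	cerebellum
Vermis_1_2	cerebellum
Vermis_3	cerebellum
Vermis_4_5	cerebellum
Vermis_6	cerebellum
Vermis_7	cerebellum
Vermis_8	cerebellum
Vermis_9	cerebellum
Vermis_10	cerebellum
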