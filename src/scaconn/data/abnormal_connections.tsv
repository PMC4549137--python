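label_i	region_i	label_j	region_j	p	direction
Right cerebellum crus II	Cerebelum_Crus2_R	Left Middle Frontal Gyrus	Frontal_Mid_L	0.00005	decrease
Left superior temporal pole	Temporal_Pole_Sup_L	Right Inferior Triangular Frontal Gyrus	Frontal_Inf_Tri_R	0.00005	increase
Right cerebellum 10	Cerebelum_10_R	Right Cerebellum 3	Cerebelum_3_R	0.00011	decrease
Left cerebellum 9	Cerebelum_9_L	Left Fusiform Gyrus	Fusiform_L	0.00016	increase
Left inferior temporal gyrus	Temporal_Inf_L	Left Precuneus	Precuneus_L	0.00023	increase
Right cerebellum crus II	Cerebelum_Crus2_R	Left Inferior Triangular Frontal Gyrus	Frontal_Inf_Tri_L	0.00027	decrease
Left middle temporal pole	Temporal_Pole_Mid_L	Right Hippocampus	Hippocampus_R	0.00034	increase
Right middle temporal gyrus	Temporal_Mid_R	Right Middle Occipital Gyrus	Occipital_Mid_R	0.00034	increase
Left cerebellum crus II	Cerebelum_Crus2_L	Left Middle Frontal Gyrus	Frontal_Mid_L	0.00048	decrease
Left cerebellum 9	Cerebelum_9_L	Left Inferior Occipital Gyrus	Occipital_Inf_L	0.00048	increase
Left middle frontal gyrus	Frontal_Mid_L	Right Superior Frontal Gyrus	Frontal_Sup_R	0.00050	increase
Left cerebellum 9	Cerebelum_9_L	Right Superior Frontal Gyrus	Frontal_Sup_R	0.00053	decrease
Vermis 3	Vermis_3	Right Cerebellum 10	Cerebelum_10_R	0.00055	decrease
Right inferior temporal gyrus	Temporal_Inf_R	Left Precuneus	Precuneus_L	0.00060	increase
Left superior temporal pole	Temporal_Pole_Sup_L	Right Inferior Opercular Frontal Gyrus	Frontal_Inf_Oper_R	0.00062	increase
Right cerebellum 7	Cerebelum_7b_R	Left Middle Frontal Gyrus	Frontal_Mid_L	0.00065	decrease
Left cerebellum 7	Cerebelum_7b_L	Left Inferior Occipital Gyrus	Occipital_Inf_L	0.00069	increase
Left cuneus	Cuneus_L	Left Inferior Frontal Gyrus	Frontal_Inf_Oper_L	0.00069	decrease
Left cerebellum 9	Cerebelum_9_L	Right Medial Superior Frontal Gyrus	Frontal_Sup_Medial_R	0.00094	decrease
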