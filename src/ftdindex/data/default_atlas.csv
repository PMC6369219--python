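name,hemisphere,lobe,cortical
l_precentral_gyrus,left,frontal,true
l_precentral_gyrus_medial_segment,left,frontal,true
l_superior_frontal_gyrus,left,frontal,true
l_superior_frontal_gyrus_medial_segment,left,frontal,true
l_middle_frontal_gyrus,left,frontal,true
l_inferior_frontal_gyrus_pars_opercularis,left,frontal,true
l_inferior_frontal_gyrus_pars_triangularis,left,frontal,true
l_inferior_frontal_gyrus_pars_orbitalis,left,frontal,true
l_frontal_pole,left,frontal,true
l_fronto_marginal_gyrus,left,frontal,true
l_frontal_operculum,left,frontal,true
l_central_operculum,left,frontal,true
l_supplementary_motor_cortex,left,frontal,true
l_anterior_orbital_gyrus,left,frontal,true
l_medial_orbital_gyrus,left,frontal,true
l_lateral_orbital_gyrus,left,frontal,true
l_posterior_orbital_gyrus,left,frontal,true
l_gyrus_rectus,left,frontal,true
l_subcallosal_area,left,frontal,true
l_anterior_cingulate_gyrus,left,frontal,true
l_middle_cingulate_gyrus,left,frontal,true
l_medial_frontal_cortex,left,frontal,true
l_temporal_pole,left,temporal,true
l_superior_temporal_gyrus,left,temporal,true
l_middle_temporal_gyrus,left,temporal,true
l_middle_temporal_gyrus_temporooccipital_part,left,temporal,true
l_inferior_temporal_gyrus,left,temporal,true
l_fusiform_gyrus,left,temporal,true
l_parahippocampal_gyrus,left,temporal,true
l_entorhinal_area,left,temporal,true
l_transverse_temporal_gyrus,left,temporal,true
l_planum_polare,left,temporal,true
l_planum_temporale,left,temporal,true
l_superior_temporal_sulcus_bank,left,temporal,true
l_postcentral_gyrus,left,parietal,true
l_postcentral_gyrus_medial_segment,left,parietal,true
l_superior_parietal_lobule,left,parietal,true
l_supramarginal_gyrus,left,parietal,true
l_angular_gyrus,left,parietal,true
l_precuneus,left,parietal,true
l_posterior_cingulate_gyrus,left,parietal,true
l_parietal_operculum,left,parietal,true
l_intraparietal_sulcus_region,left,parietal,true
l_occipital_pole,left,occipital,true
l_superior_occipital_gyrus,left,occipital,true
l_middle_occipital_gyrus,left,occipital,true
l_inferior_occipital_gyrus,left,occipital,true
l_cuneus,left,occipital,true
l_calcarine_cortex,left,occipital,true
l_lingual_gyrus,left,occipital,true
l_occipital_fusiform_gyrus,left,occipital,true
r_precentral_gyrus,right,frontal,true
r_precentral_gyrus_medial_segment,right,frontal,true
r_superior_frontal_gyrus,right,frontal,true
r_superior_frontal_gyrus_medial_segment,right,frontal,true
r_middle_frontal_gyrus,right,frontal,true
r_inferior_frontal_gyrus_pars_opercularis,right,frontal,true
r_inferior_frontal_gyrus_pars_triangularis,right,frontal,true
r_inferior_frontal_gyrus_pars_orbitalis,right,frontal,true
r_frontal_pole,right,frontal,true
r_fronto_marginal_gyrus,right,frontal,true
r_frontal_operculum,right,frontal,true
r_central_operculum,right,frontal,true
r_supplementary_motor_cortex,right,frontal,true
r_anterior_orbital_gyrus,right,frontal,true
r_medial_orbital_gyrus,right,frontal,true
r_lateral_orbital_gyrus,right,frontal,true
r_posterior_orbital_gyrus,right,frontal,true
r_gyrus_rectus,right,frontal,true
r_subcallosal_area,right,frontal,true
r_anterior_cingulate_gyrus,right,frontal,true
r_middle_cingulate_gyrus,right,frontal,true
r_medial_frontal_cortex,right,frontal,true
r_temporal_pole,right,temporal,true
r_superior_temporal_gyrus,right,temporal,true
r_middle_temporal_gyrus,right,temporal,true
r_middle_temporal_gyrus_temporooccipital_part,right,temporal,true
r_inferior_temporal_gyrus,right,temporal,true
r_fusiform_gyrus,right,temporal,true
r_parahippocampal_gyrus,right,temporal,true
r_entorhinal_area,right,temporal,true
r_transverse_temporal_gyrus,right,temporal,true
r_planum_polare,right,temporal,true
r_planum_temporale,right,temporal,true
r_superior_temporal_sulcus_bank,right,temporal,true
r_postcentral_gyrus,right,parietal,true
r_postcentral_gyrus_medial_segment,right,parietal,true
r_superior_parietal_lobule,right,parietal,true
r_supramarginal_gyrus,right,parietal,true
r_angular_gyrus,right,parietal,true
r_precuneus,right,parietal,true
r_posterior_cingulate_gyrus,right,parietal,true
r_parietal_operculum,right,parietal,true
r_intraparietal_sulcus_region,right,parietal,true
r_occipital_pole,right,occipital,true
r_superior_occipital_gyrus,right,occipital,true
r_middle_occipital_gyrus,right,occipital,true
r_inferior_occipital_gyrus,right,occipital,true
r_cuneus,right,occipital,true
r_calcarine_cortex,right,occipital,true
r_lingual_gyrus,right,occipital,true
r_occipital_fusiform_gyrus,right,occipital,true
l_hippocampus,left,subcortical_or_other,false
l_amygdala,left,subcortical_or_other,false
l_thalamus,left,subcortical_or_other,false
l_caudate_nucleus,left,subcortical_or_other,false
l_putamen,left,subcortical_or_other,false
l_globus_pallidus,left,subcortical_or_other,false
l_nucleus_accumbens,left,subcortical_or_other,false
l_ventral_diencephalon,left,subcortical_or_other,false
l_anterior_insula,left,subcortical_or_other,false
l_posterior_insula,left,subcortical_or_other,false
l_cerebellum_cortex,left,subcortical_or_other,false
l_cerebellum_white_matter,left,subcortical_or_other,false
l_lateral_ventricle,left,subcortical_or_other,false
r_hippocampus,right,subcortical_or_other,false
r_amygdala,right,subcortical_or_other,false
r_thalamus,right,subcortical_or_other,false
r_caudate_nucleus,right,subcortical_or_other,false
r_putamen,right,subcortical_or_other,false
r_globus_pallidus,right,subcortical_or_other,false
r_nucleus_accumbens,right,subcortical_or_other,false
r_ventral_diencephalon,right,subcortical_or_other,false
r_anterior_insula,right,subcortical_or_other,false
r_posterior_insula,right,subcortical_or_other,false
r_cerebellum_cortex,right,subcortical_or_other,false
r_cerebellum_white_matter,right,subcortical_or_other,false
r_lateral_ventricle,right,subcortical_or_other,false
brainstem,midline,subcortical_or_other,false
cerebellar_vermis,midline,subcortical_or_other,false
corpus_callosum,midline,subcortical_or_other,false
third_ventricle,midline,subcortical_or_other,false
fourth_ventricle,midline,subcortical_or_other,false
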