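name,level,source_class,family,collation
n_buds,object,tumor_bud,count,sum
n_pdc,object,pdc,count,sum
n_lvi,object,lvi,count,sum
n_minimal_lvi,object,minimal_lvi,count,sum
n_vessels,object,vessel,count,sum
lvd_per_mm2,object,vessel,density,mean
tumor_stroma_pct,roi,tumor,density,mean
area_pdc_um2,object,pdc,sum_area,sum
tumor_bud_sum_area_um2,object,tumor_bud,sum_area,sum
tumor_bud_mean_area_um2,object,tumor_bud,mean_area,mean
tumor_bud_sd_area_um2,object,tumor_bud,sd_area,mean
tumor_bud_mean_roundness,object,tumor_bud,shape,mean
tumor_bud_mean_elongation,object,tumor_bud,shape,mean
tumor_bud_mean_nuclei,object,tumor_bud,count,mean
pdc_sum_area_um2,object,pdc,sum_area,sum
pdc_mean_area_um2,object,pdc,mean_area,mean
pdc_sd_area_um2,object,pdc,sd_area,mean
pdc_mean_roundness,object,pdc,shape,mean
pdc_mean_elongation,object,pdc,shape,mean
pdc_mean_nuclei,object,pdc,count,mean
lvi_sum_area_um2,object,lvi,sum_area,sum
lvi_mean_area_um2,object,lvi,mean_area,mean
lvi_sd_area_um2,object,lvi,sd_area,mean
lvi_mean_roundness,object,lvi,shape,mean
lvi_mean_elongation,object,lvi,shape,mean
lvi_mean_nuclei,object,lvi,count,mean
minimal_lvi_sum_area_um2,object,minimal_lvi,sum_area,sum
minimal_lvi_mean_area_um2,object,minimal_lvi,mean_area,mean
minimal_lvi_sd_area_um2,object,minimal_lvi,sd_area,mean
minimal_lvi_mean_roundness,object,minimal_lvi,shape,mean
minimal_lvi_mean_elongation,object,minimal_lvi,shape,mean
minimal_lvi_mean_nuclei,object,minimal_lvi,count,mean
tumor_bud_mean_dist_to_tumor_um,object,tumor_bud,spatial_distance,mean
tumor_bud_min_dist_to_tumor_um,object,tumor_bud,spatial_distance,mean
pdc_mean_dist_to_tumor_um,object,pdc,spatial_distance,mean
pdc_min_dist_to_tumor_um,object,pdc,spatial_distance,mean
vessel_sum_area_um2,object,vessel,sum_area,sum
vessel_mean_area_um2,object,vessel,mean_area,mean
vessel_sd_area_um2,object,vessel,sd_area,mean
vessel_mean_elongation,object,vessel,shape,mean
tumor_area_um2,roi,tumor,sum_area,sum
stroma_area_um2,roi,stroma,sum_area,sum
lumen_necrosis_area_um2,roi,lumen_necrosis,sum_area,sum
tissue_area_mm2,roi,tissue,sum_area,sum
n_nuclei_tumor,nucleus,tumor,count,sum
n_nuclei_stroma,nucleus,stroma,count,sum
n_nuclei_tumor_bud,nucleus,tumor_bud,count,sum
n_nuclei_pdc,nucleus,pdc,count,sum
n_nuclei_intravascular,nucleus,intravascular,count,sum
nucleus_mean_area_um2_tumor,nucleus,tumor,mean_area,mean
nucleus_mean_area_um2_stroma,nucleus,stroma,mean_area,mean
nucleus_density_per_mm2_tumor,nucleus,tumor,density,mean
nucleus_density_per_mm2_stroma,nucleus,stroma,density,mean
tumor_mean_intensity_dapi,roi,tumor,intensity,mean
tumor_sd_intensity_dapi,roi,tumor,intensity,mean
tumor_mean_intensity_panck,roi,tumor,intensity,mean
tumor_sd_intensity_panck,roi,tumor,intensity,mean
tumor_mean_intensity_d240,roi,tumor,intensity,mean
tumor_sd_intensity_d240,roi,tumor,intensity,mean
stroma_mean_intensity_dapi,roi,stroma,intensity,mean
stroma_sd_intensity_dapi,roi,stroma,intensity,mean
stroma_mean_intensity_panck,roi,stroma,intensity,mean
stroma_sd_intensity_panck,roi,stroma,intensity,mean
stroma_mean_intensity_d240,roi,stroma,intensity,mean
stroma_sd_intensity_d240,roi,stroma,intensity,mean
tumor_bud_mean_intensity_dapi,object,tumor_bud,intensity,mean
tumor_bud_sd_intensity_dapi,object,tumor_bud,intensity,mean
tumor_bud_mean_intensity_panck,object,tumor_bud,intensity,mean
tumor_bud_sd_intensity_panck,object,tumor_bud,intensity,mean
pdc_mean_intensity_dapi,object,pdc,intensity,mean
pdc_sd_intensity_dapi,object,pdc,intensity,mean
pdc_mean_intensity_panck,object,pdc,intensity,mean
pdc_sd_intensity_panck,object,pdc,intensity,mean
lvi_mean_intensity_dapi,object,lvi,intensity,mean
lvi_sd_intensity_dapi,object,lvi,intensity,mean
lvi_mean_intensity_panck,object,lvi,intensity,mean
lvi_sd_intensity_panck,object,lvi,intensity,mean
minimal_lvi_mean_intensity_dapi,object,minimal_lvi,intensity,mean
minimal_lvi_sd_intensity_dapi,object,minimal_lvi,intensity,mean
minimal_lvi_mean_intensity_panck,object,minimal_lvi,intensity,mean
minimal_lvi_sd_intensity_panck,object,minimal_lvi,intensity,mean
vessel_mean_intensity_d240,object,vessel,intensity,mean
vessel_sd_intensity_d240,object,vessel,intensity,mean
tumor_glcm_contrast_dapi,roi,tumor,texture,mean
tumor_glcm_entropy_dapi,roi,tumor,texture,mean
tumor_glcm_correlation_dapi,roi,tumor,texture,mean
tumor_glcm_contrast_panck,roi,tumor,texture,mean
tumor_glcm_entropy_panck,roi,tumor,texture,mean
tumor_glcm_correlation_panck,roi,tumor,texture,mean
stroma_glcm_contrast_dapi,roi,stroma,texture,mean
stroma_glcm_entropy_dapi,roi,stroma,texture,mean
stroma_glcm_correlation_dapi,roi,stroma,texture,mean
stroma_glcm_contrast_panck,roi,stroma,texture,mean
stroma_glcm_entropy_panck,roi,stroma,texture,mean
stroma_glcm_correlation_panck,roi,stroma,texture,mean
tumor_bud_glcm_contrast_panck,object,tumor_bud,texture,mean
tumor_bud_glcm_entropy_panck,object,tumor_bud,texture,mean
tumor_bud_glcm_correlation_panck,object,tumor_bud,texture,mean
tumor_bud_glcm_contrast_dapi,object,tumor_bud,texture,mean
tumor_bud_glcm_entropy_dapi,object,tumor_bud,texture,mean
tumor_bud_glcm_correlation_dapi,object,tumor_bud,texture,mean
pdc_glcm_contrast_panck,object,pdc,texture,mean
pdc_glcm_entropy_panck,object,pdc,texture,mean
pdc_glcm_correlation_panck,object,pdc,texture,mean
pdc_glcm_contrast_dapi,object,pdc,texture,mean
pdc_glcm_entropy_dapi,object,pdc,texture,mean
pdc_glcm_correlation_dapi,object,pdc,texture,mean
vessel_glcm_contrast_d240,object,vessel,texture,mean
vessel_glcm_entropy_d240,object,vessel,texture,mean
vessel_glcm_correlation_d240,object,vessel,texture,mean
nucleus_mean_roundness_tumor,nucleus,tumor,shape,mean
nucleus_mean_roundness_stroma,nucleus,stroma,shape,mean
tumor_bud_per_mm2,object,tumor_bud,density,mean
pdc_per_mm2,object,pdc,density,mean
lvi_per_mm2,object,lvi,density,mean
minimal_lvi_per_mm2,object,minimal_lvi,density,mean
lumen_fraction_pct,roi,lumen_necrosis,density,mean
stroma_nucleus_mean_dist_to_tumor_um,nucleus,stroma,spatial_distance,mean
bud_total_nuclei,nucleus,tumor_bud,count,sum
pdc_total_nuclei,nucleus,pdc,count,sum
vessel_mean_roundness,object,vessel,shape,mean
bud_sum_area_pct_tissue,object,tumor_bud,density,mean
pdc_sum_area_pct_tissue,object,pdc,density,mean
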