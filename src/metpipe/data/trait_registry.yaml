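# Registry of trait names recognised by the pipeline.
#
# source: "50cm_cut" (destructive sample from a 50 cm row segment) or
#         "whole_plot" (plot-level measurement, destructive or visual).
# disease: visual fungal infection scores, bounded 0-100 (% area).
# nonnegative: negative observed values are physically impossible and are
#              recoded missing during QC.
# Derived traits (computed by the pipeline, e.g. the total fungal infection
# score) carry source "derived".
traits:
  Biomass_bio:        {full_name: above-ground dry mass at maturity, source: 50cm_cut, unit: g/m2, nonnegative: true, disease: false}
  Harvest_Index_bio:  {full_name: harvest index, source: 50cm_cut, unit: "", nonnegative: true, disease: false}
  Grain_per_spike_bio: {full_name: grains per spike, source: 50cm_cut, unit: number, nonnegative: true, disease: false}
  Plantheight_bio:    {full_name: plant height, source: 50cm_cut, unit: cm, nonnegative: true, disease: false}
  Seedyield_bio:      {full_name: grain yield, source: 50cm_cut, unit: g/m2, nonnegative: true, disease: false}
  Spike_number_bio:   {full_name: spike number, source: 50cm_cut, unit: number/m2, nonnegative: true, disease: false}
  TGW_bio:            {full_name: thousand grain weight, source: 50cm_cut, unit: g, nonnegative: true, disease: false}
  BBCH59:             {full_name: heading date (75% of ears visible), source: whole_plot, unit: day_of_year, nonnegative: true, disease: false}
  BBCH87:             {full_name: maturity date (75% hard dough), source: whole_plot, unit: day_of_year, nonnegative: true, disease: false}
  Biomass:            {full_name: above-ground dry mass at maturity, source: whole_plot, unit: dt/ha, nonnegative: true, disease: false}
  Crude_protein:      {full_name: crude protein percentage per grain dry mass, source: whole_plot, unit: "%", nonnegative: true, disease: false}
  DTR:                {full_name: leaf tan spot (Drechslera tritici-repentis), source: whole_plot, unit: "% leaf area", nonnegative: true, disease: true}
  Falling_number:     {full_name: falling number, source: whole_plot, unit: s, nonnegative: true, disease: false}
  Fusarium:           {full_name: Fusarium head blight, source: whole_plot, unit: "% spike", nonnegative: true, disease: true}
  Grain:              {full_name: grain number per unit area, source: whole_plot, unit: number_x1e5/ha, nonnegative: true, disease: false}
  Leaf_rust:          {full_name: leaf rust (Puccinia triticina), source: whole_plot, unit: "% leaf area", nonnegative: true, disease: true}
  Powdery_mildew:     {full_name: powdery mildew (Blumeria graminis), source: whole_plot, unit: "% leaf area", nonnegative: true, disease: true}
  Protein_yield:      {full_name: grain protein yield, source: whole_plot, unit: dt/ha, nonnegative: true, disease: false}
  Sedimentation:      {full_name: sedimentation, source: whole_plot, unit: ml, nonnegative: true, disease: false}
  Seedyield:          {full_name: grain yield, source: whole_plot, unit: dt/ha, nonnegative: true, disease: false}
  Septoria:           {full_name: leaf spot (Septoria tritici), source: whole_plot, unit: "% leaf area", nonnegative: true, disease: true}
  Straw:              {full_name: above-ground biomass minus grain yield, source: whole_plot, unit: dt/ha, nonnegative: true, disease: false}
  Stripe_rust:        {full_name: stripe rust (Puccinia striiformis), source: whole_plot, unit: "% leaf area", nonnegative: true, disease: true}
  TGW:                {full_name: thousand grain weight, source: whole_plot, unit: g, nonnegative: true, disease: false}
  TFI:                {full_name: total fungal infection area, source: derived, unit: "% area (summed)", nonnegative: true, disease: false}
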