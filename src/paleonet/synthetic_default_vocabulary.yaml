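# Default controlled vocabularies for occurrence validation and the
# synthetic-data generator.
#
# SYNTHETIC STAND-IN: the full published category lists for Ediacaran
# taphonomic modes, paleoenvironments, morphogroups, trace architectures and
# form categories live in supplementary data tables that are not distributed
# with this package. The lists below are constructed placeholders with the
# documented category counts (8 / 17 / 33 / 24 / 22); names printed in the
# primary literature are used where available. Validation treats codes outside
# these lists as reportable, never fatal, so user-supplied vocabularies can
# replace this file via configuration.
#
# `paleoenvironments` is ordered from shallowest to deepest along a model
# marine transect; the ordering is meaningful for biotope analyses.

preservational_modes:
  - ediacara_type_cast_mold
  - carbonaceous_compression
  - skeletal
  - secondarily_mineralized_tube
  - agglutinated_test
  - trace_impression
  - permineralized
  - three_dimensional_mold

paleoenvironments:
  - fluvial_deltaic
  - tidal_flat
  - lagoon
  - upper_shoreface
  - lower_shoreface
  - offshore_transition
  - offshore_shelf
  - inner_ramp
  - mid_ramp
  - outer_ramp
  - carbonate_platform
  - reef_margin
  - carbonate_slope_and_basin
  - siliciclastic_slope
  - turbiditic_slope
  - basin_plain
  - abyssal_fan

morphogroups:
  - rangeomorph
  - arboreomorph
  - dickinsoniomorph
  - bilateralomorph
  - kimberellomorph
  - triradialomorph
  - tetraradialomorph
  - pentaradialomorph
  - octoradialomorph
  - frondomorph
  - erniettomorph
  - palaeopascichnid
  - tubular_organic
  - tubular_mineralized
  - cloudinomorph
  - anabaritid
  - protoconulariid
  - sponge_grade
  - filamentous_alga
  - strap_shaped_alga
  - ribbon_shaped_alga
  - dendritic_alga
  - globular_alga
  - vendotaenid
  - sabelliditid
  - discoidal
  - bag_shaped
  - mat_encruster
  - coenocytic_protist
  - agglutinated_tubular
  - problematic_bilaterian
  - problematic_radial
  - incertae_sedis

trace_architectures:
  - simple_horizontal_trail
  - sinuous_trail
  - meandering_trail
  - guided_meander
  - spiral_burrow
  - horizontal_burrow
  - branched_horizontal_burrow
  - vertical_burrow
  - u_shaped_burrow
  - plug_shaped_burrow
  - spreite_burrow
  - radial_trace
  - rosette_trace
  - star_shaped_trace
  - scratch_array
  - resting_trace
  - locomotion_trace
  - grazing_trace
  - feeding_excavation
  - network_burrow_system
  - boxwork_burrow_system
  - treptichnid_probe
  - arthropod_trackway
  - undermat_mining

form_categories:
  - frond
  - disc
  - mat
  - tube
  - shell
  - simple_trace
  - complex_trace
  - flat_vendobiont
  - quilted_vendobiont
  - filamentous_alga_form
  - ribbon_alga_form
  - strap_alga_form
  - radial_form
  - bilaterian_body
  - holdfast
  - colonial_form
  - sponge_form
  - problematicum
  - protist_form
  - agglutinated_form
  - other_skeletal
  - other_compression

paleocommunities:
  - Avalon
  - White_Sea
  - Miaohe
  - Nama

taxon_flags:
  - disc_shaped
  - possible_taphomorph
  - possible_pseudofossil
  - possible_synonym
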