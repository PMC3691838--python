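metric,zone,timepoint,value,sd
component_pixels,applicator,baseline,45050.0,23273.0
component_pixels,applicator,day3,2031.3,2637.8
component_pixels,applicator,month1,11714.1,12851.5
component_pixels,applicator,month4,14118.8,7941.5
component_pixels,applicator,month7,38592.5,25383.8
component_pixels,central,baseline,42589.6,16506.1
component_pixels,central,day3,1552.1,2688.3
component_pixels,central,month1,15663.8,15369.3
component_pixels,central,month4,14048.4,7681.3
component_pixels,central,month7,30116.7,18365.5
component_pixels,distal,baseline,41421.3,6598.9
component_pixels,distal,day3,11056.3,6637.8
component_pixels,distal,month1,21918.8,21252.3
component_pixels,distal,month4,30116.7,24992.7
component_pixels,distal,month7,37814.6,18680.4
nerve_fibre_components,applicator,baseline,50.0,34.7
nerve_fibre_components,applicator,day3,4.2,3.6
nerve_fibre_components,applicator,month1,23.4,16.4
nerve_fibre_components,applicator,month4,31.3,22.8
nerve_fibre_components,applicator,month7,53.8,26.0
nerve_fibre_components,central,baseline,52.1,25.5
nerve_fibre_components,central,day3,2.1,3.6
nerve_fibre_components,central,month1,15.0,13.0
nerve_fibre_components,central,month4,12.5,5.1
nerve_fibre_components,central,month7,66.7,36.1
nerve_fibre_components,distal,baseline,50.0,40.3
nerve_fibre_components,distal,day3,25.0,22.5
nerve_fibre_components,distal,month1,14.1,16.4
nerve_fibre_components,distal,month4,22.9,7.2
nerve_fibre_components,distal,month7,70.8,18.0
skeleton_pixels,applicator,baseline,13715.6,7004.1
skeleton_pixels,applicator,day3,622.9,809.2
skeleton_pixels,applicator,month1,3456.3,3774.2
skeleton_pixels,applicator,month4,4300.0,2411.0
skeleton_pixels,applicator,month7,11622.5,7566.4
skeleton_pixels,central,baseline,12876.0,5053.8
skeleton_pixels,central,day3,460.4,797.5
skeleton_pixels,central,month1,4627.5,4483.7
skeleton_pixels,central,month4,4217.2,2308.7
skeleton_pixels,central,month7,9110.4,5497.3
skeleton_pixels,distal,baseline,12722.5,1979.2
skeleton_pixels,distal,day3,3347.9,2056.2
skeleton_pixels,distal,month1,6585.9,6253.7
skeleton_pixels,distal,month4,9077.1,7387.1
skeleton_pixels,distal,month7,11422.9,5671.4
single_nerve_fibres,applicator,baseline,240.6,184.0
single_nerve_fibres,applicator,day3,4.2,3.6
single_nerve_fibres,applicator,month1,37.5,39.9
single_nerve_fibres,applicator,month4,40.6,25.8
single_nerve_fibres,applicator,month7,188.8,133.4
single_nerve_fibres,central,baseline,235.4,167.5
single_nerve_fibres,central,day3,6.3,10.8
single_nerve_fibres,central,month1,51.3,68.4
single_nerve_fibres,central,month4,96.9,112.9
single_nerve_fibres,central,month7,116.7,85.1
single_nerve_fibres,distal,baseline,162.5,84.7
single_nerve_fibres,distal,day3,47.9,28.2
single_nerve_fibres,distal,month1,126.6,127.5
single_nerve_fibres,distal,month4,175.0,197.3
single_nerve_fibres,distal,month7,189.6,108.7
average_single_fibre_length_um,applicator,baseline,83.4,34.3
average_single_fibre_length_um,applicator,day3,166.4,154.1
average_single_fibre_length_um,applicator,month1,101.1,52.4
average_single_fibre_length_um,applicator,month4,147.3,77.4
average_single_fibre_length_um,applicator,month7,74.2,13.5
average_single_fibre_length_um,central,baseline,74.4,31.2
average_single_fibre_length_um,central,day3,84.3,0
average_single_fibre_length_um,central,month1,151.9,65.7
average_single_fibre_length_um,central,month4,83.8,46.1
average_single_fibre_length_um,central,month7,89.2,19.4
average_single_fibre_length_um,distal,baseline,100.2,37.8
average_single_fibre_length_um,distal,day3,93.5,60.7
average_single_fibre_length_um,distal,month1,61.1,7.9
average_single_fibre_length_um,distal,month4,74.4,22
average_single_fibre_length_um,distal,month7,68.8,7.2
nerve_fibre_density_mm_per_mm2,applicator,baseline,15.142,7.93
nerve_fibre_density_mm_per_mm2,applicator,day3,0.693,0.908
nerve_fibre_density_mm_per_mm2,applicator,month1,3.896,4.315
nerve_fibre_density_mm_per_mm2,applicator,month4,4.713,2.638
nerve_fibre_density_mm_per_mm2,applicator,month7,12.945,8.586
nerve_fibre_density_mm_per_mm2,central,baseline,14.207,5.553
nerve_fibre_density_mm_per_mm2,central,day3,0.527,0.913
nerve_fibre_density_mm_per_mm2,central,month1,5.322,5.205
nerve_fibre_density_mm_per_mm2,central,month4,4.736,2.538
nerve_fibre_density_mm_per_mm2,central,month7,10.031,6.221
nerve_fibre_density_mm_per_mm2,distal,baseline,13.827,2.279
nerve_fibre_density_mm_per_mm2,distal,day3,3.725,2.302
nerve_fibre_density_mm_per_mm2,distal,month1,7.471,7.278
nerve_fibre_density_mm_per_mm2,distal,month4,10.151,8.627
nerve_fibre_density_mm_per_mm2,distal,month7,12.643,6.348
connectivity_points,applicator,baseline,14.2,10.4
connectivity_points,applicator,day3,0,0
connectivity_points,applicator,month1,1.3,2.5
connectivity_points,applicator,month4,5.6,6.6
connectivity_points,applicator,month7,13,11.5
connectivity_points,central,baseline,14.2,6.5
connectivity_points,central,day3,0,0
connectivity_points,central,month1,2.0,3.3
connectivity_points,central,month4,1.3,2.5
connectivity_points,central,month7,13.3,10.4
connectivity_points,distal,baseline,13.0,9.6
connectivity_points,distal,day3,1.7,1.4
connectivity_points,distal,month1,5.6,6.6
connectivity_points,distal,month4,8.3,8.8
connectivity_points,distal,month7,12.5,9.0
branches,applicator,baseline,104.2,91.8
branches,applicator,day3,0,0
branches,applicator,month1,7.8,15.6
branches,applicator,month4,4.7,6.0
branches,applicator,month7,73.8,64.1
branches,central,baseline,101.0,101.6
branches,central,day3,2.1,3.6
branches,central,month1,18.8,35.1
branches,central,month4,45.3,59.2
branches,central,month7,25.0,33.1
branches,distal,baseline,61.3,43.6
branches,distal,day3,12.5,16.5
branches,distal,month1,62.5,61.0
branches,distal,month4,87.5,120.5
branches,distal,month7,58.3,54.6
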