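characteristic,n_2019,pct_2019,n_2020,pct_2020,printed_diff_pct
patients_total,287936,,287965,,0.01
visits_total,1421779,,1402406,,-1.36
visits_face_to_face,1212800,85.30,633858,45.20,-47.74
visits_telemedicine,208979,14.70,768548,54.80,267.76
visits_general_medicine,859153,60.43,822433,58.64,-4.27
visits_nursing,427959,30.10,473051,33.73,10.54
visits_pediatrics,134667,9.47,106922,7.62,-20.60
visits_early_childhood,95098,6.69,76460,5.45,-24.38
visits_childhood,57436,4.04,52101,3.72,-10.24
visits_adolescence,55768,3.92,61693,4.40,9.60
visits_youth,55943,3.93,69287,4.94,19.26
visits_adulthood,475366,33.43,514327,36.67,7.58
visits_older_adult,682168,47.98,628538,44.82,-8.53
codes_total,2079680,,1912342,,-10.57
codes_per_visit_mean,1.46,,1.36,,-6.84
codes_per_visit_sd,1.00,,0.89,,
visits_male,641602,45.13,627806,44.77,-2.15
visits_female,780074,54.87,774486,55.23,-0.72
age_mean,53.54,,52.89,,-1.21
age_sd,26.25,,25.72,,
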