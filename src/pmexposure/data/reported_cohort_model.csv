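factor,level,emm,coefficient
model,intercept,,8.545
model,idw,,0.279
model,indoor:idw,,-0.168
indoor,outdoor,5.800,
indoor,indoor,5.297,0.520
landuse,other,6.154,
landuse,commercial,5.830,-0.324
landuse,industrial,6.726,0.571
landuse,office,3.511,-2.643
landuse,park_open_space,5.391,-0.763
landuse,public_facilities,5.808,-0.346
landuse,residential,6.511,0.357
landuse,vehicle,4.461,-1.694
season,spring,6.740,
season,summer,2.835,-3.905
season,autumn,5.429,-1.312
season,winter,7.191,0.451
hour,0,5.712,
hour,1,5.014,-0.698
hour,2,5.165,-0.547
hour,3,4.677,-1.035
hour,4,4.264,-1.448
hour,5,3.853,-1.859
hour,6,4.042,-1.670
hour,7,4.881,-0.831
hour,8,4.735,-0.977
hour,9,4.485,-1.227
hour,10,5.018,-0.694
hour,11,4.889,-0.823
hour,12,5.100,-0.613
hour,13,5.001,-0.711
hour,14,4.871,-0.841
hour,15,4.855,-0.858
hour,16,5.195,-0.517
hour,17,5.997,0.285
hour,18,8.097,2.385
hour,19,8.327,2.614
hour,20,7.925,2.212
hour,21,7.190,1.478
hour,22,7.190,1.477
hour,23,6.688,0.975
age_group,0-29,9.175,
age_group,30-39,5.058,-4.116
age_group,40-49,3.962,-5.213
age_group,50-59,6.460,-2.714
age_group,60+,3.089,-6.085
sex,female,6.491,
sex,male,4.607,-1.884
marital,unmarried,5.503,
marital,married,5.594,0.091
race,non-white,4.011,
race,white,7.087,3.076
edu,lt_ba,5.065,
edu,ba,6.747,1.682
edu,gt_ba,4.834,-0.231
income,low,5.535,
income,high,5.563,0.028
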