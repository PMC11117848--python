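activity,scenario,axis,mean,sd,n,unit
gait,activity_average,ap,52.22,45.16,8,N
gait,activity_average,ie,0.89,0.90,8,Nm
gait,activity_average,comp,223.81,118.80,8,N
gait,activity_average,vv,4.20,3.95,8,Nm
gait,activity_average,flexion,0.69,0.16,8,deg
step_down,activity_average,ap,23.46,22.71,9,N
step_down,activity_average,ie,0.81,0.47,9,Nm
step_down,activity_average,comp,185.48,46.73,9,N
step_down,activity_average,vv,2.69,0.61,9,Nm
step_down,activity_average,flexion,2.11,0.39,9,deg
dkb,activity_average,ap,39.95,29.40,9,N
dkb,activity_average,ie,1.15,1.22,9,Nm
dkb,activity_average,comp,189.07,98.88,9,N
dkb,activity_average,vv,1.67,0.73,9,Nm
dkb,activity_average,flexion,1.69,0.40,9,deg
gait,patient_specific,ap,29.35,11.81,8,N
gait,patient_specific,ie,0.74,0.20,8,Nm
gait,patient_specific,comp,151.54,55.48,8,N
gait,patient_specific,vv,2.77,0.64,8,Nm
gait,patient_specific,flexion,0.61,0.09,8,deg
step_down,patient_specific,ap,25.16,18.69,9,N
step_down,patient_specific,ie,0.57,0.34,9,Nm
step_down,patient_specific,comp,97.26,53.82,9,N
step_down,patient_specific,vv,2.07,0.58,9,Nm
step_down,patient_specific,flexion,2.08,0.45,9,deg
dkb,patient_specific,ap,31.17,19.63,9,N
dkb,patient_specific,ie,0.65,0.54,9,Nm
dkb,patient_specific,comp,44.37,22.03,9,N
dkb,patient_specific,vv,0.81,0.32,9,Nm
dkb,patient_specific,flexion,1.63,0.37,9,deg
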