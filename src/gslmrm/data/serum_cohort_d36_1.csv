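# Quantified serum amounts (fmol, per-injection equivalents) of seven
# ganglioside classes (d18:1/18:0 species) in 36 unaffected controls,
# two Tay-Sachs patients (TSD) and one Sandhoff patient (SD).
# Age in years except where suffixed: d days, w weeks, m months.
group,sample_id,sex,age,GM3 d36:1,GM2 d36:1,GM1 d36:1,GD3 d36:1,GD2 d36:1,GD1 d36:1,GT1 d36:1
control,CS01,M,3,476.9,372.4,110.3,212.9,173.5,102.9,31.0
control,CS02,F,11,497.2,125.6,66.5,109.6,108.5,70.8,19.4
control,CS03,M,8,236.3,58.2,26.5,113.4,85.6,63.5,22.5
control,CS04,M,13,674.1,124.6,70.7,81.3,122.9,68.0,26.9
control,CS05,M,3,368.9,104.8,61.7,170.5,139.5,144.7,19.9
control,CS06,F,7,296.1,68.7,32.7,130.8,78.0,70.4,17.4
control,CS07,F,4w,374.6,192.0,57.0,186.5,137.4,104.2,39.9
control,CS08,F,4,369.6,107.0,85.7,99.0,98.7,58.4,16.3
control,CS09,F,3,400.9,183.3,73.7,184.5,101.7,70.4,20.0
control,CS10,M,13,361.3,85.4,60.2,96.1,99.1,69.5,16.6
control,CS11,F,9,355.7,58.3,25.7,165.0,157.8,101.2,34.4
control,CS12,F,20,327.4,105.2,61.5,163.4,85.2,95.9,24.6
control,CS13,F,19,318.4,366.7,44.7,167.7,147.2,76.3,25.0
control,CS14,F,2m,440.5,213.6,65.2,484.9,180.9,298.9,100.9
control,CS15,M,3w,534.2,96.8,41.3,132.8,103.9,84.4,24.6
control,CS16,M,20,319.5,145.5,46.3,241.2,155.2,114.3,43.7
control,CS17,F,9,405.6,90.3,38.4,303.0,111.6,126.5,51.7
control,CS18,F,5m,492.4,229.3,110.6,175.1,88.3,173.6,54.9
control,CS19,M,3,491.4,134.6,94.5,356.8,62.8,154.9,38.7
control,CS20,F,3,388.7,578.0,93.9,239.5,110.8,113.3,30.0
control,CS21,M,15,402.0,104.8,95.1,240.1,142.1,67.8,33.9
control,CS22,M,11,357.9,268.0,159.5,413.6,101.6,213.9,61.8
control,CS23,F,9,378.5,193.5,80.4,303.8,41.8,98.7,33.8
control,CS24,M,5,297.2,193.7,105.5,289.7,52.3,187.1,58.4
control,CS25,F,5d,452.0,134.0,76.0,112.8,63.3,43.9,14.3
control,CS26,M,5,275.4,345.1,170.1,365.5,85.3,190.5,59.7
control,CS27,F,16m,441.1,115.0,71.8,322.2,32.0,109.4,33.3
control,CS28,F,3m,296.6,384.0,136.4,260.3,57.5,201.3,52.3
control,CS29,F,26m,465.1,166.7,117.4,254.3,56.5,196.8,58.9
control,CS30,M,17,535.9,124.0,93.4,108.1,33.3,99.2,27.6
control,CS31,M,10,297.5,177.6,176.6,162.9,140.4,112.6,27.2
control,CS32,F,4w,355.0,306.2,83.7,323.6,45.3,116.0,38.4
control,CS33,M,3,294.0,284.6,215.8,356.1,61.6,126.0,28.9
control,CS34,M,8,431.3,381.7,209.8,566.0,76.2,206.5,71.0
control,CS35,M,20,429.5,584.6,184.3,283.2,39.3,110.3,31.1
control,CS36,M,23,465.9,106.9,36.3,317.3,131.7,122.7,16.5
tay_sachs,TSD01,F,3,251.7,2905.3,464.8,161.2,107.2,85.2,24.0
tay_sachs,TSD02,M,5,224.2,1929.1,627.6,319.3,167.4,190.1,27.8
sandhoff,SD01,M,7,199.6,1273.1,471.5,221.3,99.2,57.1,16.5
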