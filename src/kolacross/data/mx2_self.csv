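cross_label,pod_set_pct,pseudo_pod_set_pct,number_of_pods,pod_weight,nuts_per_pod,weight_unpeeled,weight_peeled,outturn,brix,potential_alcohol,firmness
A10 × A10,28.2,0.0,15.7,151.9,7.0,64.6,54.1,83.2,10.4,8.2,14.3
A1 × A1,48.6,0.0,30.1,297.0,5.0,46.2,32.0,70.0,10.9,7.8,13.1
A12 × A12,35.1,12.5,20.5,202.6,4.7,43.4,30.9,71.4,9.3,7.1,12.7
A2 × A2,28.1,11.0,18.2,179.3,6.7,60.9,47.6,78.6,7.7,6.1,15.0
A22 × A22,25.1,16.4,15.7,156.1,4.3,39.7,29.4,73.8,11.1,7.7,14.6
A26 × A26,29.5,19.0,16.8,166.0,4.7,42.4,33.2,78.2,13.4,6.4,15.0
A8 × A8,34.9,0.0,22.9,227.1,7.0,64.6,49.2,77.2,12.2,8.7,13.6
Atta 1 × Atta 1,27.3,6.4,15.8,156.6,5.0,45.2,33.9,74.9,15.2,10.5,14.7
Atta 3 × Atta 3,13.7,12.8,6.1,59.3,4.0,35.9,25.9,70.1,15.2,8.4,13.5
Club × Club,30.3,9.0,20.4,201.5,6.3,59.1,48.1,80.8,18.1,6.4,15.8
JB 1 × JB 1,48.7,0.0,27.7,274.3,6.3,59.1,47.1,79.5,15.7,7.0,14.4
JB 10 × JB 10,28.5,18.6,15.6,152.6,5.3,47.9,36.7,76.0,18.8,7.2,14.9
JB 15 × JB 15,21.7,0.0,10.9,106.5,6.3,59.1,48.4,81.3,10.2,6.5,15.7
JB 17 × JB 17,24.2,17.4,12.2,118.7,5.0,45.2,34.8,76.8,13.6,6.7,13.5
JB 19 × JB 19,15.3,20.9,9.7,93.1,4.7,42.4,33.6,79.0,18.8,7.6,16.1
JB 26 × JB 26,30.0,0.0,21.6,207.9,5.7,51.7,42.7,80.6,17.1,5.3,12.2
JB 3 × JB 3,22.8,16.6,13.3,131.0,6.3,58.1,46.9,80.6,16.7,4.5,15.7
JB 32 × JB 32,27.3,20.9,12.1,119.3,4.3,39.7,30.8,77.0,5.7,7.6,13.9
JB 35 × JB 35,18.7,0.0,12.1,116.4,6.0,56.4,45.8,79.4,6.1,7.8,12.9
JB 36 × JB 36,37.0,0.0,22.8,222.4,5.7,51.7,41.4,80.2,7.3,6.2,13.4
JB 37 × JB 37,41.9,0.0,24.1,234.6,5.7,52.6,42.0,78.5,12.9,4.8,14.1
JB 40 × JB 40,29.3,0.0,15.7,155.5,5.0,46.2,34.6,74.6,12.7,7.7,14.5
JB 9 × JB 9,36.4,0.0,19.3,189.2,7.0,64.6,52.6,81.5,11.0,9.5,13.0
JB 34 × JB 34,33.5,0.0,21.7,208.4,6.7,60.9,49.7,81.5,9.0,8.8,15.6
P2-1B × P2-1B,26.0,21.8,14.5,140.3,6.7,62.9,50.9,79.2,17.9,7.5,16.7
P2-1c × P2-1c,34.0,0.0,20.6,201.4,4.7,43.4,31.7,73.0,12.6,6.6,16.2
W25 × W25,27.6,24.3,15.7,156.1,5.7,52.7,40.8,77.4,10.8,5.0,14.0
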