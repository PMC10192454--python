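cross_label,pod_set_pct,pseudo_pod_set_pct,number_of_pods,pod_weight,nuts_per_pod,weight_unpeeled,weight_peeled,outturn,brix,potential_alcohol,firmness
GX1/1 × GX1/1,35.1,14.0,15.0,159.5,8.8,88.7,61.7,69.1,15.1,6.5,13.2
GX1/16 × GX1/16,48.6,0.0,20.0,210.8,12.1,122.5,81.4,70.0,9.8,6.6,12.1
GX1/2 × GX1/2,5.4,3.9,2.4,25.6,1.6,16.7,11.2,46.4,5.6,4.0,10.1
GX1/21 × GX1/21,34.1,6.9,12.0,125.8,7.5,75.9,53.7,70.3,7.7,7.3,13.5
GX1/24 × GX1/24,26.5,20.3,10.0,104.6,6.5,66.5,49.3,75.7,13.5,7.9,16.7
GX1/25 × GX1/25,1.9,1.9,0.9,8.6,0.6,5.7,5.1,29.8,3.4,3.1,5.2
GX1/27 × GX1/27,51.0,15.2,19.7,206.8,12.2,124.5,79.7,67.3,12.8,5.7,13.3
GX1/29 × GX1/29,26.4,5.9,10.8,112.9,6.3,63.0,50.5,79.3,9.9,6.9,11.5
GX1/3 × GX1/3,5.9,18.4,2.6,27.7,1.6,15.9,11.0,69.9,11.5,8.2,13.6
GX1/30 × GX1/30,50.9,5.1,25.7,270.4,13.7,139.5,79.3,62.1,11.3,8.3,12.9
GX1/35 × GX1/35,15.1,6.7,5.9,61.8,3.8,38.3,23.9,66.2,12.0,7.1,14.4
GX1/36 × GX1/36,32.6,10.0,13.8,144.9,8.5,86.2,70.7,81.7,17.0,7.3,14.8
GX1/37 × GX1/37,47.1,6.8,20.8,217.4,12.8,129.5,82.2,64.6,14.9,8.0,12.9
GX1/38 × GX1/38,11.8,8.7,4.4,46.8,2.6,26.2,17.9,69.7,14.6,7.2,15.4
GX1/4 × GX1/4,40.0,7.8,17.3,181.2,10.6,107.8,72.8,69.2,13.2,6.6,14.7
GX1/50 × GX1/50,41.3,13.5,16.9,178.8,9.9,99.4,78.3,78.5,14.0,6.9,15.1
GX1/53 × GX1/53,6.8,7.5,3.5,38.2,2.0,20.4,12.9,43.5,5.7,4.0,9.6
GX1/60 × GX1/60,35.8,3.9,15.7,165.8,8.7,86.4,71.8,82.4,11.5,8.1,14.3
GX1/64 × GX1/64,33.3,6.7,17.0,189.6,6.3,56.3,41.3,73.3,12.9,5.6,16.4
GX1/74 × GX1/74,31.2,7.1,10.3,103.2,7.8,81.7,60.8,74.1,11.7,8.8,13.8
GX1/7 × GX1/7,29.5,9.1,11.2,117.2,6.9,70.2,56.0,81.4,14.0,5.5,15.3
GX1/71 × GX1/71,12.0,3.9,5.3,55.4,3.2,31.9,23.7,76.4,8.4,8.0,15.7
GX1/72 × GX1/72,4.2,2.1,2.0,21.2,1.0,9.5,7.9,55.3,11.5,5.0,10.6
GX1/75 × GX1/75,28.3,13.3,11.8,123.7,7.5,76.7,59.3,78.3,13.0,7.7,14.0
GX1/82 × GX1/82,26.6,16.0,12.6,133.9,7.2,72.0,53.9,74.1,14.7,7.7,15.2
GX1/83 × GX1/83,31.1,12.5,12.7,132.3,8.1,82.4,58.7,69.7,11.0,7.7,13.7
GX1/86 × GX1/86,23.0,2.2,9.0,93.8,5.3,52.8,41.0,77.3,13.7,7.8,16.0
GX1/87 × GX1/87,54.3,6.1,21.7,228.0,13.2,134.0,74.6,58.4,10.5,7.3,16.1
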