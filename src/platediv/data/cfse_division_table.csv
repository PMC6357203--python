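sort,timepoint,mfi,percent_divided
Sort-1,initial,high,15.5
Sort-2,initial,high,14.3
Sort-3,initial,high,10.9
Sort-4,initial,high,16.4
Sort-5,initial,high,12.0
Sort-6,initial,high,38.5
Sort-7,initial,high,15.6
Sort-8,initial,high,22.1
Sort-9,initial,high,15.6
Sort-10,initial,high,14.3
Sort-11,initial,high,12.7
Sort-12,initial,high,8.2
Sort-1,initial,low,9.4
Sort-2,initial,low,7.9
Sort-3,initial,low,6.3
Sort-4,initial,low,10.9
Sort-5,initial,low,11.1
Sort-6,initial,low,20.3
Sort-7,initial,low,11.4
Sort-8,initial,low,45.3
Sort-9,initial,low,11.8
Sort-10,initial,low,8.0
Sort-11,initial,low,3.9
Sort-12,initial,low,3.5
Sort-1,6h,high,41.4
Sort-2,6h,high,39.7
Sort-3,6h,high,27.5
Sort-4,6h,high,64.5
Sort-5,6h,high,70.4
Sort-1,6h,low,43.4
Sort-2,6h,low,41.8
Sort-3,6h,low,27.7
Sort-4,6h,low,37.7
Sort-5,6h,low,24.6
Sort-1,20h,high,90.6
Sort-2,20h,high,87.3
Sort-3,20h,high,81.1
Sort-4,20h,high,76.4
Sort-5,20h,high,83.3
Sort-6,20h,high,93.8
Sort-7,20h,high,89.5
Sort-8,20h,high,80.4
Sort-9,20h,high,60.6
Sort-10,20h,high,91.7
Sort-11,20h,high,95.9
Sort-12,20h,high,96.0
Sort-1,20h,low,97.0
Sort-2,20h,low,86.5
Sort-3,20h,low,34.5
Sort-4,20h,low,62.4
Sort-5,20h,low,48.1
Sort-6,20h,low,96.5
Sort-7,20h,low,70.7
Sort-8,20h,low,90.0
Sort-9,20h,low,68.8
Sort-10,20h,low,67.5
Sort-11,20h,low,92.3
Sort-12,20h,low,91.3
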