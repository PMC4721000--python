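patient_id,cure_index,components,cycles,biologics,radiotherapy
01,1,5-FU,,,1
01,2,5-FU+FA+irinotecan,8,,0
01,3,5-FU,1,,0
02,1,5-FU+FA+oxaliplatin,4,,0
02,2,5-FU+FA+oxaliplatin,4,,0
02,3,5-FU+FA+oxaliplatin,4,,0
03,1,5-FU,1,,0
03,2,,4,panitumumab,0
03,3,,,,0
04,1,5-FU+FA+oxaliplatin,4,bevacizumab,0
04,2,5-FU+FA+oxaliplatin,4,bevacizumab,0
04,3,,4,bevacizumab,0
05,1,5-FU+FA+oxaliplatin,6,bevacizumab,0
05,2,5-FU+FA+oxaliplatin,4,bevacizumab,0
05,3,,,bevacizumab,0
06,1,5-FU+FA+irinotecan,4,bevacizumab,0
06,2,5-FU+FA+irinotecan,4,bevacizumab,0
06,3,,4,bevacizumab,0
07,1,5-FU,3,,0
07,2,5-FU,4,,0
07,3,5-FU,1,,0
08,1,5-FU+FA+oxaliplatin,3,,0
08,2,5-FU+FA+oxaliplatin,4,,0
08,3,5-FU+FA+irinotecan,4,,0
09,1,5-FU+FA+oxaliplatin,4,,0
09,2,5-FU+FA+irinotecan,4,bevacizumab,0
09,3,5-FU+FA+irinotecan,4,,0
10,1,5-FU+FA+oxaliplatin,8,,0
10,2,5-FU+FA+oxaliplatin,4,,0
10,3,,,,0
11,1,5-FU,3,,0
11,2,,,,0
11,3,,,,0
12,1,5-FU+FA+irinotecan,4,bevacizumab,0
12,2,5-FU+FA+irinotecan,4,bevacizumab,0
12,3,,4,bevacizumab,0
13,1,5-FU,3,,0
13,2,5-FU,2,,0
13,3,5-FU,2,,0
14,1,5-FU+FA+oxaliplatin,8,,0
14,2,5-FU+FA,4,,0
14,3,,,,0
15,1,5-FU+FA+oxaliplatin,4,bevacizumab,0
15,2,5-FU+FA+oxaliplatin,9,bevacizumab,0
15,3,,,,0
16,1,5-FU+FA+oxaliplatin,6,,0
16,2,5-FU+FA+oxaliplatin,4,,0
16,3,5-FU+FA+oxaliplatin,4,,0
17,1,5-FU+FA+oxaliplatin,7,bevacizumab,0
17,2,5-FU+FA+oxaliplatin,5,bevacizumab,0
17,3,,,,0
18,1,5-FU+FA+oxaliplatin,4,,0
18,2,5-FU+FA+oxaliplatin,5,bevacizumab,0
18,3,,,,0
19,1,5-FU,3,,0
19,2,5-FU,3,,0
19,3,5-FU,3,,0
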