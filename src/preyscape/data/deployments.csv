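shark_id,sex,length_m,n_locations,printed_duration_h,start_local,end_local
WS3_2018,M,6,4,13.8,2018-05-15 13:17:02,2018-05-16 03:03:00
WS11_2018,M,8,4,14.6,2018-05-16 13:20:02,2018-05-17 03:55:00
WS17_2018,M,7,8,14.9,2018-05-17 14:16:00,2018-05-18 05:12:00
WS18_2018,F,7,9,24.3,2018-05-18 12:51:00,2018-05-19 13:10:27
WS25_2018,M,6,4,22.6,2018-05-19 11:20:00,2018-05-20 09:58:01
WS29_2018,M,6,17,26.9,2018-05-19 11:55:00,2018-05-20 14:46:00
WS39_2018,M,,2,36.3,2018-05-20 11:43:00,2018-05-21 23:59:59
WS41_2018,M,6,14,20.9,2018-05-20 13:04:00,2018-05-21 09:55:15
WS51_2018,M,8,7,34.5,2018-05-21 13:27:01,2018-05-22 23:59:59
WS58_2018,M,6,4,25.5,2018-05-22 12:43:00,2018-05-23 14:12:58
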